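"""Sample metadata: id, age, sex, histological subtype (ACP or PCP)."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SUBTYPES = ("ACP", "PCP")


@dataclass
class SampleMeta:
    sample_id: str
    age: int
    sex: str  # "M" / "F"
    subtype: str

    def __post_init__(self):
        if self.subtype not in SUBTYPES:
            raise ValueError(f"subtype must be one of {SUBTYPES}, got {self.subtype!r}")
        if self.age < 0:
            raise ValueError("age must be non-negative")


def write_sample_metadata(samples: list[SampleMeta], path) -> None:
    df = pd.DataFrame(
        [(s.sample_id, s.age, s.sex, s.subtype) for s in samples],
        columns=["sample_id", "age", "sex", "subtype"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_sample_metadata(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleMeta(str(r.sample_id), int(r.age), str(r.sex), str(r.subtype))
        for r in df.itertuples()
    ]
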