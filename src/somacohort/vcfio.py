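"""VCF reading and writing for per-caller call sets and normal panels.

All call sets use one fixed VCF v4.2 dialect: single-tumor, sites-only
records with the caller's evidence in INFO keys documented in the header —

    NDP  normal-sample read depth at the locus
    TDP  tumor-sample read depth
    TAD  tumor alt-supporting reads
    VAF  tumor variant allele fraction
    MBQ  mean base quality at the locus (Phred)
    VP   caller p-value (InDel callers only)

Positions are 1-based as in VCF; pysam exposes 0-based starts, converted at
this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

_INFO_FIELDS = [
    ("NDP", "1", "Integer", "Normal sample read depth at the locus"),
    ("TDP", "1", "Integer", "Tumor sample read depth at the locus"),
    ("TAD", "1", "Integer", "Tumor alt-supporting read count"),
    ("VAF", "1", "Float", "Tumor variant allele fraction"),
    ("MBQ", "1", "Float", "Mean base quality at the locus (Phred)"),
    ("VP", "1", "Float", "Caller p-value for the variant"),
]


@dataclass
class CallRecord:
    """One candidate variant as emitted by a single caller."""

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    passed: bool = True
    info: dict = field(default_factory=dict)

    @property
    def variant_type(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNV"
        return "INS" if len(self.alt_allele) > len(self.ref_allele) else "DEL"

    @property
    def key(self) -> tuple:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


def _make_header(contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for ident, number, vtype, desc in _INFO_FIELDS:
        header.info.add(ident, number, vtype, desc)
    header.filters.add("artifact_lod", None, None, "Caller-internal confidence filter")
    return header


def write_vcf(path, records: list[CallRecord], contigs: dict[str, int]) -> None:
    """Write call records as an uncompressed sites-only VCF."""
    header = _make_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        order = {c: i for i, c in enumerate(contigs)}
        for rec in sorted(records, key=lambda r: (order[r.chromosome], r.position, r.alt_allele)):
            vr = out.new_record(
                contig=rec.chromosome,
                start=rec.position - 1,
                alleles=(rec.ref_allele, rec.alt_allele),
            )
            vr.filter.add("PASS" if rec.passed else "artifact_lod")
            for k, v in rec.info.items():
                if v is not None:
                    vr.info[k] = v
            out.write(vr)


def read_vcf(path) -> list[CallRecord]:
    """Read a VCF written in the package dialect back into call records."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = {}
            for k in ("NDP", "TDP", "TAD", "VAF", "MBQ", "VP"):
                if k in rec.info:
                    v = rec.info[k]
                    info[k] = round(float(v), 6) if isinstance(v, float) else v
            passed = "PASS" in rec.filter or len(rec.filter) == 0
            out.append(
                CallRecord(
                    chromosome=rec.chrom,
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    passed=passed,
                    info=info,
                )
            )
    return out
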