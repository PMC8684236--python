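"""Six-class and 96-trinucleotide-context mutational spectra.

Single-base substitutions are collapsed onto the pyrimidine strand: a
mutation reported with a purine reference (A or G) is reverse-complemented,
flanks swapped, so each substitution falls into one of six base-pair classes
(C:G>A:T ... T:A>G:C) and, with its 5'/3' flanking bases, into one of 96
trinucleotide channels written ``X[R>A]Y``.

Channel order is the conventional one used for signature interchange:
substitution groups C>A, C>G, C>T, T>A, T>C, T>G, each expanded over the 16
flank pairs in lexicographic order (A_A, A_C, ... T_T).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The six pyrimidine-strand substitutions, in canonical order.
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Six base-pair substitution class labels, index-aligned with SUBSTITUTIONS.
CLASS6_LABELS = ("C:G>A:T", "C:G>G:C", "C:G>T:A", "T:A>A:T", "T:A>C:G", "T:A>G:C")

_BASES = "ACGT"

#: The 96 channel labels in canonical order (group-major, flanks lexicographic).
CHANNELS_96 = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in _BASES for f3 in _BASES
)

CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


class SpectrumError(ValueError):
    """Raised for malformed substitution inputs or reference mismatches."""


def six_class(ref: str, alt: str) -> str:
    """Classify a single-base substitution into one of six base-pair classes.

    Purine references are collapsed to their pyrimidine complement, so
    ``G>A`` and ``C>T`` both map to ``C:G>T:A``.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT":
        raise SpectrumError(f"non-ACGT substitution {ref}>{alt}")
    if ref == alt:
        raise SpectrumError(f"ref and alt are identical ({ref})")
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return CLASS6_LABELS[SUBSTITUTIONS.index(f"{ref}>{alt}")]


def collapse_to_context96(ref: str, alt: str, flank5: str, flank3: str) -> str:
    """Return the pyrimidine-strand channel label for a substitution.

    ``flank5``/``flank3`` are the reference-strand bases immediately 5' and
    3' of the mutated base. If the reference base is a purine, the whole
    triplet is reverse-complemented (flanks swap).

    Raises :class:`SpectrumError` if any base is not A/C/G/T (an N flank
    makes the context undefined).
    """
    ref, alt = ref.upper(), alt.upper()
    flank5, flank3 = flank5.upper(), flank3.upper()
    for b in (ref, alt, flank5, flank3):
        if b not in "ACGT":
            raise SpectrumError(f"non-ACGT base {b!r} in context")
    if ref == alt:
        raise SpectrumError(f"ref and alt are identical ({ref})")
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        flank5, flank3 = COMPLEMENT[flank3], COMPLEMENT[flank5]
    return f"{flank5}[{ref}>{alt}]{flank3}"


def channel_to_class6(channel: str) -> str:
    """Map a 96-channel label to its six-class label."""
    return CLASS6_LABELS[CHANNEL_INDEX[channel] // 16]


@dataclass
class SpectrumVector:
    """Per-sample substitution spectrum.

    ``counts6`` is always the 16-flank marginal of ``counts96``.
    ``n_excluded`` counts SNVs dropped because a flank was N or the variant
    sat at a chromosome edge.
    """

    sample_id: str
    counts96: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=np.int64))
    n_excluded: int = 0

    @property
    def counts6(self) -> np.ndarray:
        return self.counts96.reshape(6, 16).sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts96.sum())

    @property
    def proportions96(self) -> np.ndarray | None:
        """96-channel proportions, or None when the spectrum is empty."""
        t = self.total
        if t == 0:
            return None
        return self.counts96 / t

    @property
    def proportions6(self) -> np.ndarray | None:
        t = self.total
        if t == 0:
            return None
        return self.counts6 / t


def sample_spectrum(variants, sequences, sample_id: str = "") -> SpectrumVector:
    """Tally the 96-channel spectrum of a sample's SNVs.

    Parameters
    ----------
    variants
        Iterable of objects with ``chromosome``, ``position`` (1-based),
        ``ref_allele`` and ``alt_allele`` attributes. Only single-base
        substitutions are expected; InDels are rejected.
    sequences
        Mapping of chromosome name to sequence string (or any object
        supporting slice access returning str, e.g. a pyfaidx record).

    The reference allele of every variant is checked against the genome;
    mismatches are collected and raised together as a consistency error.
    """
    vec = SpectrumVector(sample_id=sample_id)
    mismatches = []
    for v in variants:
        ref, alt = v.ref_allele.upper(), v.alt_allele.upper()
        if len(ref) != 1 or len(alt) != 1:
            raise SpectrumError(
                f"sample_spectrum expects SNVs only, got {ref}>{alt} at "
                f"{v.chromosome}:{v.position}"
            )
        seq = sequences[v.chromosome]
        pos0 = v.position - 1
        if pos0 < 0 or pos0 >= len(seq):
            raise SpectrumError(
                f"position {v.chromosome}:{v.position} beyond chromosome end"
            )
        genome_ref = str(seq[pos0]).upper()
        if genome_ref != ref:
            mismatches.append(f"{v.chromosome}:{v.position} {ref}!={genome_ref}")
            continue
        if pos0 == 0 or pos0 == len(seq) - 1:
            vec.n_excluded += 1
            continue
        f5 = str(seq[pos0 - 1]).upper()
        f3 = str(seq[pos0 + 1]).upper()
        try:
            channel = collapse_to_context96(ref, alt, f5, f3)
        except SpectrumError:
            vec.n_excluded += 1
            continue
        vec.counts96[CHANNEL_INDEX[channel]] += 1
    if mismatches:
        raise SpectrumError(
            "reference allele mismatches: " + "; ".join(mismatches[:20])
        )
    return vec


def cohort_spectrum_table(spectra: list[SpectrumVector]) -> pd.DataFrame:
    """96 x n_samples count table, rows in canonical channel order."""
    data = {s.sample_id: s.counts96 for s in spectra}
    return pd.DataFrame(data, index=list(CHANNELS_96))


def pooled_spectrum(spectra: list[SpectrumVector]) -> SpectrumVector:
    """Cohort-wide spectrum obtained by pooling counts across samples."""
    pooled = SpectrumVector(sample_id="cohort")
    for s in spectra:
        pooled.counts96 = pooled.counts96 + s.counts96
        pooled.n_excluded += s.n_excluded
    return pooled


def mean_proportion_spectrum(spectra: list[SpectrumVector]) -> np.ndarray:
    """Cohort spectrum as the mean of per-sample proportions (non-empty samples)."""
    props = [s.proportions96 for s in spectra if s.total > 0]
    if not props:
        return np.zeros(96)
    return np.mean(props, axis=0)
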