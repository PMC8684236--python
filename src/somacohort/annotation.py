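"""Region and coding-effect classification against a gene model.

Region taxonomy is exonic / intronic / intergenic: a variant overlapping
any CDS of any transcript is exonic (exonic takes precedence over an
intronic assignment from an overlapping transcript); a variant within a
transcript span but outside all CDS is intronic; everything else is
intergenic.

Coding effects for SNVs are derived by strand-aware codon substitution and
translation with the standard genetic code: silent, missense, or nonsense
(stop gained, written ``X``). Coding InDels are classed ``indel``, named as
an in-frame deletion/insertion when the length change is a multiple of 3
and as a frameshift (``p.<aa><pos>fs``) otherwise.

When several transcripts overlap a variant, the one with the longest CDS is
reported; ties break on alphabetical gene name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .genome import GeneModel, Transcript

REGION_CLASSES = ("exonic", "intronic", "intergenic")
EFFECT_CLASSES = ("missense", "silent", "nonsense", "indel", "none")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotatedVariant:
    sample_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_type: str
    region_class: str
    effect_class: str  # "none" outside CDS
    protein_change: str | None  # present iff effect_class != "none"
    gene_name: str | None = None

    @property
    def key(self):
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


def _affected_interval(position: int, ref: str, alt: str) -> tuple[int, int]:
    """1-based closed genomic interval touched by the variant.

    Deletions use the full REF footprint beyond the anchor base; insertions
    and SNVs affect the anchor position only.
    """
    if len(ref) > len(alt):  # deletion
        return (position + 1, position + len(ref) - 1)
    return (position, position)


def translate_codon(codon: str) -> str:
    aa = str(Seq(codon).translate())
    return "X" if aa == "*" else aa


class GenomeAnnotator:
    """Classifies variants against a gene model plus reference sequences."""

    def __init__(self, model: GeneModel, sequences):
        self.model = model
        self.sequences = sequences
        self._cds_trees: dict[str, IntervalTree] = {}
        self._span_trees: dict[str, IntervalTree] = {}
        self._cds_cache: dict[str, str] = {}
        self._warned_chroms: set[str] = set()
        for tx in model.transcripts:
            ct = self._cds_trees.setdefault(tx.chromosome, IntervalTree())
            st = self._span_trees.setdefault(tx.chromosome, IntervalTree())
            for s, e in tx.cds:
                ct.addi(s, e + 1, tx)  # half-open on 1-based coords
            s, e = tx.span
            st.addi(s, e + 1, tx)

    def _cds_seq(self, tx: Transcript) -> str:
        if tx.transcript_id not in self._cds_cache:
            self._cds_cache[tx.transcript_id] = tx.cds_sequence(self.sequences)
        return self._cds_cache[tx.transcript_id]

    def _overlapping_cds_transcripts(self, chrom, start, end) -> list[Transcript]:
        tree = self._cds_trees.get(chrom)
        if tree is None:
            return []
        hits = {iv.data.transcript_id: iv.data for iv in tree.overlap(start, end + 1)}
        return sorted(hits.values(), key=lambda t: (-t.cds_length, t.gene_name))

    def classify_region(self, variant) -> str:
        chrom = variant.chromosome
        if chrom not in self._span_trees:
            if chrom not in self._warned_chroms:
                self._warned_chroms.add(chrom)
                warnings.warn(
                    f"chromosome {chrom} absent from the gene model; "
                    "classifying as intergenic"
                )
            return "intergenic"
        s, e = _affected_interval(variant.position, variant.ref_allele,
                                  variant.alt_allele)
        if self._overlapping_cds_transcripts(chrom, s, e):
            return "exonic"
        if self._span_trees[chrom].overlap(s, e + 1):
            return "intronic"
        return "intergenic"

    def classify_effect(self, variant) -> tuple[str, str | None, str | None]:
        """(effect_class, protein_change, gene_name) for an exonic variant."""
        s, e = _affected_interval(variant.position, variant.ref_allele,
                                  variant.alt_allele)
        transcripts = self._overlapping_cds_transcripts(variant.chromosome, s, e)
        if not transcripts:
            raise AnnotationError(
                f"variant {variant.chromosome}:{variant.position} does not "
                "overlap any CDS"
            )
        tx = transcripts[0]
        is_snv = len(variant.ref_allele) == 1 and len(variant.alt_allele) == 1
        if is_snv:
            return self._snv_effect(variant, tx)
        return self._indel_effect(variant, tx)

    def _snv_effect(self, variant, tx: Transcript):
        off = tx.genomic_to_cds(variant.position)
        if off is None:
            raise AnnotationError(
                f"{variant.chromosome}:{variant.position} outside CDS of "
                f"{tx.transcript_id}"
            )
        cds = self._cds_seq(tx)
        codon_i, within = divmod(off, 3)
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        ref_tx = variant.ref_allele if tx.strand == "+" else _COMP[variant.ref_allele]
        alt_tx = variant.alt_allele if tx.strand == "+" else _COMP[variant.alt_allele]
        if codon[within] != ref_tx:
            raise AnnotationError(
                f"reference mismatch at {variant.chromosome}:{variant.position}"
                f" in {tx.transcript_id}: CDS has {codon[within]}, call has "
                f"{ref_tx}"
            )
        new_codon = codon[:within] + alt_tx + codon[within + 1 :]
        aa_ref = translate_codon(codon)
        aa_alt = translate_codon(new_codon)
        pos_aa = codon_i + 1
        if aa_alt == aa_ref:
            return "silent", f"p.{aa_ref}{pos_aa}{aa_ref}", tx.gene_name
        if aa_alt == "X":
            return "nonsense", f"p.{aa_ref}{pos_aa}X", tx.gene_name
        return "missense", f"p.{aa_ref}{pos_aa}{aa_alt}", tx.gene_name

    def _indel_effect(self, variant, tx: Transcript):
        ref, alt = variant.ref_allele, variant.alt_allele
        delta = len(ref) - len(alt)
        cds = self._cds_seq(tx)
        if delta > 0:  # deletion
            s, e = _affected_interval(variant.position, ref, alt)
            offs = [tx.genomic_to_cds(p) for p in (s, e)]
            offs = [o for o in offs if o is not None]
            if not offs:
                # footprint touches CDS via the tree but endpoints fell in
                # introns; report a generic coding indel
                return "indel", "p.?", tx.gene_name
            first, last = min(offs), max(offs)
            aa1, aa2 = first // 3 + 1, last // 3 + 1
            if delta % 3 == 0:
                a1 = translate_codon(cds[(aa1 - 1) * 3 : (aa1 - 1) * 3 + 3])
                a2 = translate_codon(cds[(aa2 - 1) * 3 : (aa2 - 1) * 3 + 3])
                return "indel", f"p.{a1}{aa1}_{a2}{aa2}del", tx.gene_name
            a1 = translate_codon(cds[(aa1 - 1) * 3 : (aa1 - 1) * 3 + 3])
            return "indel", f"p.{a1}{aa1}fs", tx.gene_name
        # insertion
        off = tx.genomic_to_cds(variant.position)
        if off is None:
            return "indel", "p.?", tx.gene_name
        aa1 = off // 3 + 1
        a1 = translate_codon(cds[(aa1 - 1) * 3 : (aa1 - 1) * 3 + 3])
        if (-delta) % 3 == 0:
            return "indel", f"p.{a1}{aa1}ins{-delta // 3}", tx.gene_name
        return "indel", f"p.{a1}{aa1}fs", tx.gene_name

    def annotate(self, variant, sample_id: str | None = None) -> AnnotatedVariant:
        region = self.classify_region(variant)
        effect, change, gene = "none", None, None
        if region == "exonic":
            effect, change, gene = self.classify_effect(variant)
        vt = getattr(variant, "variant_type", None)
        if vt is None:
            vt = "SNV" if len(variant.ref_allele) == len(variant.alt_allele) == 1 \
                else ("INS" if len(variant.alt_allele) > len(variant.ref_allele)
                      else "DEL")
        return AnnotatedVariant(
            sample_id=sample_id or getattr(variant, "sample_id", ""),
            chromosome=variant.chromosome,
            position=variant.position,
            ref_allele=variant.ref_allele,
            alt_allele=variant.alt_allele,
            variant_type=vt,
            region_class=region,
            effect_class=effect,
            protein_change=change,
            gene_name=gene,
        )


def annotate_cohort(variants_by_sample: dict, model: GeneModel,
                    sequences) -> dict:
    """Annotate every sample's retained variants; returns sample -> list."""
    annotator = GenomeAnnotator(model, sequences)
    return {
        sid: [annotator.annotate(v, sample_id=sid) for v in vs]
        for sid, vs in variants_by_sample.items()
    }


def annotation_table(annotated_by_sample: dict) -> pd.DataFrame:
    rows = []
    for sid, vs in annotated_by_sample.items():
        for v in vs:
            rows.append(
                (sid, v.chromosome, v.position, v.ref_allele, v.alt_allele,
                 v.variant_type, v.region_class, v.effect_class,
                 v.protein_change or "", v.gene_name or "")
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chromosome", "position", "ref", "alt", "type",
                 "region_class", "effect_class", "protein_change", "gene"],
    )
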