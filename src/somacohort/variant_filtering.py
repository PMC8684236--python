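"""Consensus and threshold filtering of multi-caller somatic call sets.

The final somatic set for a tumor is built in three steps:

1. merge the three callers' records on (chrom, pos, ref, alt), keeping the
   union of caller provenance and taking evidence from caller A when
   present, else B, else C (the InDel p-value always comes from caller C);
2. apply the consensus rule — an SNV survives only if caller A called it
   with PASS status; an InDel survives only if callers B and C both called
   it;
3. apply the threshold rules, all evaluated (no short-circuiting):

   ============== =====================================================
   VAF            variant allele fraction >= 0.10
   BQ             mean base quality >= 20
   DEPTH_NORMAL   SNV: normal depth strictly > 14
   DEPTH_TUMOR    SNV: tumor depth strictly > 8
   INDEL_DEPTH    InDel: tumor depth strictly > 10
   INDEL_P        InDel called by C: p-value <= 0.001
   PON            (chrom, pos, alt) not in the panel of normals
   MASK           no overlap with the low-complexity mask (InDels use the
                  full REF footprint)
   ============== =====================================================

Depth cut-offs read "over N" strictly; every threshold is configurable via
:class:`FilterThresholds`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .vcfio import CallRecord, read_vcf

CALLER_A = "A_mutect2like"
CALLER_B = "B_strelka2like"
CALLER_C = "C_varscan2like"

RULE_VAF = "VAF"
RULE_BQ = "BQ"
RULE_DEPTH_NORMAL = "DEPTH_NORMAL"
RULE_DEPTH_TUMOR = "DEPTH_TUMOR"
RULE_INDEL_DEPTH = "INDEL_DEPTH"
RULE_INDEL_P = "INDEL_P"
RULE_PON = "PON"
RULE_MASK = "MASK"
RULE_CALLER_CONSENSUS = "CALLER_CONSENSUS"


class InputError(ValueError):
    pass


@dataclass
class RawCall:
    """One candidate variant in one tumor, with merged caller evidence."""

    sample_id: str
    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    variant_type: str  # SNV / INS / DEL
    callers: frozenset
    passed_primary: bool
    normal_depth: int
    tumor_depth: int
    tumor_alt_reads: int
    vaf: float
    mean_base_quality: float
    indel_pvalue: float | None = None

    @property
    def key(self) -> tuple:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


@dataclass
class PanelOfNormals:
    background_sites: set  # {(chrom, pos, alt)}
    n_normals: int

    def __contains__(self, site: tuple) -> bool:
        return site in self.background_sites


@dataclass
class FilterThresholds:
    min_vaf: float = 0.10
    min_bq: float = 20.0
    min_normal_depth: int = 14  # strict: depth must be > this
    min_tumor_depth: int = 8
    min_indel_depth: int = 10
    max_indel_p: float = 0.001


@dataclass
class FilterDecision:
    failed_rules: list = field(default_factory=list)

    @property
    def retained(self) -> bool:
        return not self.failed_rules


def build_normal_panel(normal_call_files, min_supporting_normals: int = 1
                       ) -> PanelOfNormals:
    """Collect (chrom, pos, alt) sites seen in enough normal call files.

    A site enters the panel iff observed in >= ``min_supporting_normals``
    distinct normals. Contradictory reference alleles at one site raise an
    input error naming the site.
    """
    if not normal_call_files:
        raise InputError("at least one normal call file is required")
    counts: Counter = Counter()
    refs: dict = {}
    for path in normal_call_files:
        seen = set()
        for rec in read_vcf(path):
            site = (rec.chromosome, rec.position, rec.alt_allele)
            prev = refs.setdefault((rec.chromosome, rec.position), rec.ref_allele)
            if prev != rec.ref_allele:
                raise InputError(
                    f"contradictory reference alleles at "
                    f"{rec.chromosome}:{rec.position} ({prev} vs {rec.ref_allele})"
                )
            if site not in seen:
                seen.add(site)
                counts[site] += 1
    sites = {s for s, n in counts.items() if n >= min_supporting_normals}
    return PanelOfNormals(background_sites=sites, n_normals=len(normal_call_files))


def write_panel_vcf(panel: PanelOfNormals, path, contigs: dict,
                    reference_lookup=None) -> None:
    """Serialize the panel as a sites-only VCF (REF from the genome when given)."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    order = {c: i for i, c in enumerate(contigs)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for chrom, pos, alt in sorted(panel.background_sites,
                                      key=lambda s: (order[s[0]], s[1], s[2])):
            ref = "N"
            if reference_lookup is not None:
                ref = str(reference_lookup[chrom][pos - 1]).upper()
            if ref == alt:
                continue
            rec = out.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt))
            out.write(rec)


def mask_trees(mask_intervals: dict) -> dict:
    """0-based half-open BED intervals -> per-chromosome interval trees."""
    out = {}
    for chrom, ivs in mask_intervals.items():
        tree = IntervalTree()
        for s, e in ivs:
            if e > s:
                tree.addi(s, e)
        out[chrom] = tree
    return out


def _mask_overlap(call: RawCall, trees: dict) -> bool:
    tree = trees.get(call.chromosome)
    if not tree:
        return False
    start0 = call.position - 1
    end0 = start0 + max(len(call.ref_allele), 1)  # full REF footprint
    return bool(tree.overlap(start0, end0))


def apply_threshold_filters(call: RawCall, panel: PanelOfNormals, mask: dict,
                            thresholds: FilterThresholds | None = None
                            ) -> FilterDecision:
    """Evaluate every threshold rule on one merged call; enumerate failures."""
    t = thresholds or FilterThresholds()
    if call.variant_type == "SNV" and call.indel_pvalue is not None:
        raise InputError(
            f"SNV at {call.chromosome}:{call.position} carries an InDel p-value"
        )
    failed = []
    if call.vaf < t.min_vaf:
        failed.append(RULE_VAF)
    if call.mean_base_quality < t.min_bq:
        failed.append(RULE_BQ)
    if call.variant_type == "SNV":
        if call.normal_depth <= t.min_normal_depth:
            failed.append(RULE_DEPTH_NORMAL)
        if call.tumor_depth <= t.min_tumor_depth:
            failed.append(RULE_DEPTH_TUMOR)
    else:
        if call.tumor_depth <= t.min_indel_depth:
            failed.append(RULE_INDEL_DEPTH)
        if CALLER_C in call.callers and call.indel_pvalue is not None \
                and call.indel_pvalue > t.max_indel_p:
            failed.append(RULE_INDEL_P)
    if (call.chromosome, call.position, call.alt_allele) in panel:
        failed.append(RULE_PON)
    if _mask_overlap(call, mask):
        failed.append(RULE_MASK)
    return FilterDecision(failed_rules=failed)


def caller_consensus_ok(call: RawCall) -> bool:
    """SNVs need caller A with PASS; InDels need callers B and C."""
    if call.variant_type == "SNV":
        return CALLER_A in call.callers and call.passed_primary
    return CALLER_B in call.callers and CALLER_C in call.callers


def consensus_merge(per_caller_calls: dict, sample_id: str) -> list[RawCall]:
    """Merge per-caller records for one tumor into unified raw calls.

    ``per_caller_calls`` maps caller name -> list of :class:`CallRecord`.
    Evidence priority is A, then B, then C; the InDel p-value is taken from
    caller C's record when present.
    """
    merged: dict[tuple, dict] = {}
    for caller in (CALLER_A, CALLER_B, CALLER_C):
        for rec in per_caller_calls.get(caller, []):
            ident = (rec.chromosome, rec.position, rec.alt_allele)
            entry = merged.setdefault(ident, {"records": {}, "ref": rec.ref_allele})
            if entry["ref"] != rec.ref_allele:
                raise InputError(
                    f"conflicting reference alleles at {rec.chromosome}:"
                    f"{rec.position} ({entry['ref']} vs {rec.ref_allele})"
                )
            entry["records"][caller] = rec
    out = []
    for (chrom, pos, alt), entry in merged.items():
        recs = entry["records"]
        primary = next(recs[c] for c in (CALLER_A, CALLER_B, CALLER_C) if c in recs)
        info = primary.info
        vp = None
        if CALLER_C in recs:
            vp = recs[CALLER_C].info.get("VP")
        call = RawCall(
            sample_id=sample_id,
            chromosome=chrom,
            position=pos,
            ref_allele=entry["ref"],
            alt_allele=alt,
            variant_type=primary.variant_type,
            callers=frozenset(recs),
            passed_primary=recs[CALLER_A].passed if CALLER_A in recs else False,
            normal_depth=int(info.get("NDP", 0)),
            tumor_depth=int(info.get("TDP", 0)),
            tumor_alt_reads=int(info.get("TAD", 0)),
            vaf=float(info.get("VAF", 0.0)),
            mean_base_quality=float(info.get("MBQ", 0.0)),
            indel_pvalue=None if primary.variant_type == "SNV" else vp,
        )
        out.append(call)
    out.sort(key=lambda c: (c.chromosome, c.position, c.alt_allele))
    return out


@dataclass
class SampleFilterResult:
    sample_id: str
    retained: list  # list[RawCall]
    decisions: dict  # key -> FilterDecision (consensus failures included)


def filter_sample(merged: list[RawCall], panel: PanelOfNormals, mask: dict,
                  thresholds: FilterThresholds | None = None,
                  sample_id: str = "") -> SampleFilterResult:
    retained, decisions = [], {}
    for call in merged:
        decision = apply_threshold_filters(call, panel, mask, thresholds)
        if not caller_consensus_ok(call):
            decision.failed_rules.append(RULE_CALLER_CONSENSUS)
        decisions[call.key] = decision
        if decision.retained:
            retained.append(call)
    return SampleFilterResult(sample_id=sample_id or
                              (merged[0].sample_id if merged else ""),
                              retained=retained, decisions=decisions)


def filter_cohort(merged_by_sample: dict, panel: PanelOfNormals, mask: dict,
                  thresholds: FilterThresholds | None = None) -> dict:
    """Filter every sample; returns sample_id -> SampleFilterResult."""
    return {
        sid: filter_sample(calls, panel, mask, thresholds, sample_id=sid)
        for sid, calls in merged_by_sample.items()
    }


def load_and_merge_sample(caller_vcfs: dict, sample_id: str) -> list[RawCall]:
    """Read one tumor's three caller VCFs and consensus-merge them."""
    per_caller = {caller: read_vcf(path) for caller, path in caller_vcfs.items()}
    return consensus_merge(per_caller, sample_id)


def cohort_table(results: dict) -> pd.DataFrame:
    """Cohort TSV of retained variants."""
    rows = []
    for sid, res in results.items():
        for c in res.retained:
            rows.append(
                (sid, c.chromosome, c.position, c.ref_allele, c.alt_allele,
                 c.variant_type, ";".join(sorted(c.callers)), c.vaf,
                 c.normal_depth, c.tumor_depth, c.tumor_alt_reads,
                 c.mean_base_quality,
                 "" if c.indel_pvalue is None else c.indel_pvalue)
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chromosome", "position", "ref", "alt", "type",
                 "callers", "vaf", "normal_depth", "tumor_depth",
                 "tumor_alt_reads", "mean_base_quality", "indel_pvalue"],
    )


def evaluate_against_truth(results: dict, truth_keys_by_sample: dict) -> dict:
    """Precision/recall/F1 of the retained sets against planted truth keys."""
    tp = fp = fn = 0
    for sid, truth_keys in truth_keys_by_sample.items():
        res = results.get(sid)
        got = {c.key for c in res.retained} if res else set()
        tp += len(got & truth_keys)
        fp += len(got - truth_keys)
        fn += len(truth_keys - got)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision,
            "recall": recall, "f1": f1}
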