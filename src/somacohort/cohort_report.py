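"""Cohort-level summaries and end-to-end pipeline orchestration.

Covers tumor mutational burden (mutations per callable megabase), region
and coding-effect proportion tables, the age-burden Pearson correlation,
driver tallies with a Fisher-exact formalisation of CTNNB1-like /
BRAF-V600E-like mutual exclusivity, and ``run_pipeline`` which chains the
synthetic generator through filtering, annotation, spectra, signature
refitting and kataegis into a reproducible report bundle.

Percentages are rounded half-up to two decimals; TMB to three. The default
TMB denominator, 3088.27 Mb, is the non-gap length of a human whole-genome
reference; synthetic runs pass their own genome size instead.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .samples import SampleMeta, write_sample_metadata  # noqa: F401 (re-export)

#: Non-gap human whole-genome length in Mb, the default TMB denominator.
HUMAN_GENOME_MB = 3088.27


class ReportError(ValueError):
    pass


def round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def tmb(n_mutations: int, callable_megabases: float = HUMAN_GENOME_MB) -> float:
    """Mutations per megabase, reported to 3 decimals."""
    if callable_megabases <= 0:
        raise ReportError("callable_megabases must be positive")
    if n_mutations < 0:
        raise ReportError("mutation count must be non-negative")
    return round_half_up(n_mutations / callable_megabases, 3)


def class_proportions(counts: dict, denominator: int | None = None
                      ) -> pd.DataFrame:
    """Counts and percentages (2 decimals, half-up) over an explicit denominator.

    When ``denominator`` is omitted the counts' own total is used. The
    denominator is reported alongside so every percentage recomputes from
    printed numbers.
    """
    if not counts:
        return pd.DataFrame(columns=["count", "percent", "denominator"])
    denom = denominator if denominator is not None else sum(counts.values())
    if denom <= 0:
        raise ReportError("denominator must be positive")
    rows = [
        (name, n, round_half_up(100.0 * n / denom, 2), denom)
        for name, n in counts.items()
    ]
    return pd.DataFrame(rows, columns=["class", "count", "percent", "denominator"]
                        ).set_index("class")


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson_age_correlation(ages, counts) -> CorrelationResult:
    """Pearson correlation of per-sample age against mutation count.

    p-value from the two-sided t transform with n - 2 degrees of freedom.
    """
    ages = np.asarray(ages, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(ages) != len(counts) or len(ages) < 3:
        raise ReportError("need >= 3 paired observations")
    if np.std(ages) == 0 or np.std(counts) == 0:
        raise ReportError("zero variance: correlation undefined")
    r, p = stats.pearsonr(ages, counts)
    return CorrelationResult(r=float(r), p=float(p), n=len(ages))


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table by hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with a small relative
    slack for ties, as is conventional).
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ReportError("table entries must be non-negative integers")
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0

    def prob(x: int) -> float:
        # P(X = x) for X ~ Hypergeometric(n, r1, c1)
        return (math.comb(r1, x) * math.comb(n - r1, c1 - x)) / math.comb(n, c1)

    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    p_obs = prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(1.0, total)


@dataclass
class ExclusivityResult:
    driver: str
    table: list  # [[mutant_in_subtype1, wildtype], [mutant_in_subtype2, wildtype]]
    subtypes: list
    fisher_p: float
    percent_by_subtype: dict


def driver_exclusivity(samples: list, driver_flags: dict) -> dict:
    """Per-driver subtype x mutant 2x2 tables with Fisher exact p.

    ``driver_flags`` maps driver name -> {sample_id: bool}. Samples
    carrying more than one driver are reported under ``co_mutated``, not
    suppressed: exclusivity is a finding, not an assumption.
    """
    subtypes = sorted({s.subtype for s in samples})
    results = {}
    for driver, flags in driver_flags.items():
        table = []
        pct = {}
        for st in subtypes:
            ids = [s.sample_id for s in samples if s.subtype == st]
            mut = sum(1 for sid in ids if flags.get(sid, False))
            table.append([mut, len(ids) - mut])
            pct[st] = round_half_up(100.0 * mut / len(ids), 2) if ids else float("nan")
        results[driver] = ExclusivityResult(
            driver=driver, table=table, subtypes=subtypes,
            fisher_p=fisher_exact_two_sided(table), percent_by_subtype=pct,
        )
    co_mutated = []
    for s in samples:
        carried = [d for d, flags in driver_flags.items()
                   if flags.get(s.sample_id, False)]
        if len(carried) > 1:
            co_mutated.append({"sample_id": s.sample_id, "drivers": carried})
    return {"per_driver": results, "co_mutated": co_mutated}


# ---------------------------------------------------------------------------
# End-to-end pipeline


def run_pipeline(outdir, config=None, seed: int | None = None,
                 terminal_n_perm: int = 1000) -> dict:
    """Generate a synthetic cohort and run every analysis stage on it.

    Writes the report bundle (summary.json, per_sample.tsv, proportions.tsv,
    spectra_96.tsv, exposures.tsv, kataegis.bed/tsv, rainfall.tsv,
    terminal_enrichment.json, log.txt) under ``outdir`` and returns the
    in-memory results. Deterministic for a fixed config/seed.
    """
    from . import clustering, signature_refit, spectrum as spectrum_mod
    from .annotation import annotate_cohort, annotation_table
    from .sigdata import bundled_signatures
    from .synthetic_cohort import CohortConfig, write_cohort_inputs
    from .variant_filtering import (
        build_normal_panel, cohort_table, evaluate_against_truth,
        filter_cohort, load_and_merge_sample, mask_trees,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = CohortConfig(seed=0 if seed is None else int(seed))
    elif seed is not None:
        config = dataclasses.replace(config, seed=int(seed))

    log: list[str] = []
    inputs = write_cohort_inputs(config, outdir / "inputs")
    genome, truth, files = inputs["genome"], inputs["truth"], inputs["files"]
    log.append(f"generated cohort: {len(truth.samples)} samples, "
               f"{len(truth.variants)} truth variants")

    # --- filtering -------------------------------------------------------
    panel = build_normal_panel(sorted(files.normal_vcfs.values()),
                               min_supporting_normals=1)
    trees = mask_trees(genome.low_complexity_mask)
    merged = {
        sid: load_and_merge_sample(files.tumor_vcfs[sid], sid)
        for sid in sorted(files.tumor_vcfs)
    }
    results = filter_cohort(merged, panel, trees)
    retained_by_sample = {sid: res.retained for sid, res in results.items()}
    n_retained = sum(len(v) for v in retained_by_sample.values())
    log.append(f"panel of normals: {len(panel.background_sites)} sites")
    log.append(f"filtering: {sum(len(m) for m in merged.values())} merged "
               f"candidates -> {n_retained} retained")
    perf = evaluate_against_truth(results, truth.keys_by_sample())
    log.append(f"truth comparison: precision={perf['precision']:.4f} "
               f"recall={perf['recall']:.4f} f1={perf['f1']:.4f}")
    cohort_table(results).to_csv(outdir / "retained_variants.tsv", sep="\t",
                                 index=False)

    # --- annotation -------------------------------------------------------
    annotated = annotate_cohort(retained_by_sample, genome.gene_model,
                                genome.chromosomes)
    ann_df = annotation_table(annotated)
    ann_df.to_csv(outdir / "annotated_variants.tsv", sep="\t", index=False)
    region_counts = ann_df["region_class"].value_counts().to_dict()
    coding = ann_df[ann_df["region_class"] == "exonic"]
    effect_counts = coding["effect_class"].value_counts().to_dict()
    log.append(f"annotation: {len(ann_df)} variants, {len(coding)} coding")

    # --- spectra ----------------------------------------------------------
    spectra = []
    for sid in sorted(retained_by_sample):
        snvs = [c for c in retained_by_sample[sid] if c.variant_type == "SNV"]
        spectra.append(spectrum_mod.sample_spectrum(snvs, genome.chromosomes,
                                                    sample_id=sid))
    spectrum_mod.cohort_spectrum_table(spectra).to_csv(
        outdir / "spectra_96.tsv", sep="\t", index_label="channel")
    pooled = spectrum_mod.pooled_spectrum(spectra)
    log.append(f"spectra: {pooled.total} SNVs pooled")

    # --- signature refitting ---------------------------------------------
    sigs = bundled_signatures()
    exposures = signature_refit.cohort_contributions(spectra, sigs)
    exposures.to_csv(outdir / "exposures.tsv", sep="\t")
    sig_summary = signature_refit.contribution_summary(exposures, sigs)
    log.append(f"signatures: fitted {int((~exposures['low_count']).sum())} samples")

    # --- clustering -------------------------------------------------------
    all_events = []
    rainfall_frames = []
    per_sample_kataegis = {}
    for sid in sorted(retained_by_sample):
        points = clustering.intermutation_distances(retained_by_sample[sid])
        df = clustering.rainfall_table(points)
        df.insert(0, "sample_id", sid)
        rainfall_frames.append(df)
        events = clustering.detect_kataegis(points)
        per_sample_kataegis[sid] = events
        all_events.extend(events)
    pd.concat(rainfall_frames).to_csv(outdir / "rainfall.tsv", sep="\t",
                                      index=False)
    kat_df = pd.concat(
        [clustering.kataegis_table(per_sample_kataegis[sid]).assign(sample_id=sid)
         for sid in sorted(per_sample_kataegis)],
        ignore_index=True,
    ) if all_events else clustering.kataegis_table([])
    kat_df.to_csv(outdir / "kataegis.tsv", sep="\t", index=False)
    clustering.write_kataegis_bed(all_events, outdir / "kataegis.bed")
    pooled_variants = [c for sid in sorted(retained_by_sample)
                       for c in retained_by_sample[sid]]
    enrichment = clustering.terminal_enrichment(
        pooled_variants, genome, terminal_fraction=config.terminal_fraction,
        n_perm=terminal_n_perm, seed=config.seed + 7,
    )
    enrichment.to_json(outdir / "terminal_enrichment.json")
    log.append(f"kataegis: {len(all_events)} events; terminal enrichment "
               f"p={enrichment.permutation_p:.4g}")

    # --- cohort summary ---------------------------------------------------
    genome_mb = sum(
        length - sum(e - s for s, e in genome.gap_intervals[name])
        for name, length in ((n, len(s)) for n, s in genome.chromosomes.items())
    ) / 1e6
    per_sample_rows = []
    meta_by_id = {s.sample_id: s for s in truth.samples}
    for sid in sorted(retained_by_sample):
        calls = retained_by_sample[sid]
        n_snv = sum(1 for c in calls if c.variant_type == "SNV")
        n_indel = len(calls) - n_snv
        m = meta_by_id[sid]
        per_sample_rows.append(
            (sid, m.age, m.sex, m.subtype, n_snv, n_indel,
             tmb(n_snv, genome_mb), tmb(n_indel, genome_mb))
        )
    per_sample = pd.DataFrame(
        per_sample_rows,
        columns=["sample_id", "age", "sex", "subtype", "n_snv", "n_indel",
                 "tmb_snv", "tmb_indel"],
    )
    per_sample.to_csv(outdir / "per_sample.tsv", sep="\t", index=False)

    corr = pearson_age_correlation(per_sample["age"],
                                   per_sample["n_snv"] + per_sample["n_indel"])

    # driver genotype flags from annotated coding variants
    acp_tx = genome.gene_model.get("CTNB1L-001")
    exon3 = acp_tx.cds[2]
    flags_acp = {}
    flags_pcp = {}
    for sid, anns in annotated.items():
        flags_acp[sid] = any(
            a.gene_name == "CTNB1L" and exon3[0] <= a.position <= exon3[1]
            and a.effect_class in ("missense", "nonsense", "indel")
            for a in anns
        )
        flags_pcp[sid] = any(
            a.gene_name == "BRAFL" and a.effect_class == "missense"
            and a.protein_change is not None and a.protein_change.endswith("600E")
            for a in anns
        )
    excl = driver_exclusivity(truth.samples, {
        "CTNNB1-exon3-like": flags_acp,
        "BRAF-V600E-like": flags_pcp,
    })

    prop_region = class_proportions(region_counts)
    prop_effect = class_proportions(effect_counts)
    pd.concat([prop_region.assign(table="region"),
               prop_effect.assign(table="effect")]).to_csv(
        outdir / "proportions.tsv", sep="\t")

    summary = {
        "n_samples": len(truth.samples),
        "n_truth_variants": len(truth.variants),
        "n_retained": n_retained,
        "filter_performance": perf,
        "genome_megabases": round(genome_mb, 4),
        "mean_tmb_snv": round_half_up(float(per_sample["tmb_snv"].mean()), 3),
        "mean_tmb_indel": round_half_up(float(per_sample["tmb_indel"].mean()), 3),
        "region_counts": {k: int(v) for k, v in sorted(region_counts.items())},
        "effect_counts": {k: int(v) for k, v in sorted(effect_counts.items())},
        "age_correlation": dataclasses.asdict(corr),
        "driver_exclusivity": {
            d: {
                "table": r.table,
                "subtypes": r.subtypes,
                "fisher_p": r.fisher_p,
                "percent_by_subtype": r.percent_by_subtype,
            }
            for d, r in excl["per_driver"].items()
        },
        "co_mutated": excl["co_mutated"],
        "signature_summary": {
            name: {k: (None if pd.isna(v) else round(float(v), 4))
                   for k, v in row.items() if k != "n"}
            for name, row in sig_summary.iterrows()
        },
        "n_kataegis_events": len(all_events),
        "terminal_enrichment": {
            "observed_fraction": enrichment.observed_fraction,
            "expected_fraction": enrichment.expected_fraction,
            "permutation_p": enrichment.permutation_p,
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(outdir / "log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return {
        "config": config,
        "genome": genome,
        "truth": truth,
        "results": results,
        "annotated": annotated,
        "spectra": spectra,
        "exposures": exposures,
        "kataegis": per_sample_kataegis,
        "enrichment": enrichment,
        "summary": summary,
        "per_sample": per_sample,
    }
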