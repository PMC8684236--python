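"""Shared fixtures: synthetic cohorts at two scales, built once per session."""

from __future__ import annotations

import warnings

import pytest

from somacohort.synthetic_cohort import (
    CALLER_A, CALLER_B, CALLER_C, CallerError, CohortConfig, KataegisSpec,
    emulate_caller_outputs, generate_reference, plant_somatic_mutations,
)
from somacohort.variant_filtering import (
    build_normal_panel, filter_cohort, load_and_merge_sample, mask_trees,
)

warnings.filterwarnings("ignore", message="chromosome .* absent")


def small_config(seed: int = 11, **overrides) -> CohortConfig:
    """A reduced cohort that keeps every structural feature of the default."""
    base = dict(
        n_acp=4,
        n_pcp=3,
        chromosome_lengths={"chr1": 400_000, "chr2": 300_000},
        mean_snv=150.0,
        mean_indel=12.0,
        kataegis_spec=[KataegisSpec("chr1", 200_000, 8, 3_000)],
        artifact_site_rate=4e-5,
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


def zero_noise(**overrides):
    return dict(
        caller_error={
            CALLER_A: CallerError(0.0, 0.0),
            CALLER_B: CallerError(0.0, 0.0),
            CALLER_C: CallerError(0.0, 0.0),
        },
        artifact_site_rate=0.0,
        **overrides,
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Small default-noise cohort: genome, truth, caller files, filter result."""
    cfg = small_config()
    genome = generate_reference(cfg)
    truth = plant_somatic_mutations(genome, cfg)
    outdir = tmp_path_factory.mktemp("small_cohort")
    files = emulate_caller_outputs(truth, genome, cfg, outdir)
    panel = build_normal_panel(sorted(files.normal_vcfs.values()))
    merged = {
        sid: load_and_merge_sample(files.tumor_vcfs[sid], sid)
        for sid in sorted(files.tumor_vcfs)
    }
    results = filter_cohort(merged, panel, mask_trees(genome.low_complexity_mask))
    return {
        "config": cfg,
        "genome": genome,
        "truth": truth,
        "files": files,
        "panel": panel,
        "merged": merged,
        "results": results,
    }


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """Full-size cohort at the default study conditions (26 tumor/normal pairs)."""
    cfg = CohortConfig(seed=1234)
    genome = generate_reference(cfg)
    truth = plant_somatic_mutations(genome, cfg)
    outdir = tmp_path_factory.mktemp("default_cohort")
    files = emulate_caller_outputs(truth, genome, cfg, outdir)
    panel = build_normal_panel(sorted(files.normal_vcfs.values()))
    merged = {
        sid: load_and_merge_sample(files.tumor_vcfs[sid], sid)
        for sid in sorted(files.tumor_vcfs)
    }
    results = filter_cohort(merged, panel, mask_trees(genome.low_complexity_mask))
    return {
        "config": cfg,
        "genome": genome,
        "truth": truth,
        "files": files,
        "panel": panel,
        "merged": merged,
        "results": results,
    }


@pytest.fixture(scope="session")
def small_genome(small_cohort):
    return small_cohort["genome"]
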