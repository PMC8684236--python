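"""Consensus and threshold filtering: rules, panel, oracle equivalence."""

import dataclasses

import numpy as np
import pytest

from oracles import filter_oracle_retained
from somacohort.variant_filtering import (
    CALLER_A, CALLER_B, CALLER_C, FilterThresholds, InputError, PanelOfNormals,
    RawCall, apply_threshold_filters, build_normal_panel, caller_consensus_ok,
    consensus_merge, evaluate_against_truth, filter_sample,
    mask_trees, write_panel_vcf,
)
from somacohort.vcfio import CallRecord, write_vcf

EMPTY_PANEL = PanelOfNormals(background_sites=set(), n_normals=0)
NO_MASK = {}


def make_call(**overrides) -> RawCall:
    base = dict(
        sample_id="s1", chromosome="chr1", position=1000, ref_allele="C",
        alt_allele="T", variant_type="SNV", callers=frozenset({CALLER_A, CALLER_B}),
        passed_primary=True, normal_depth=20, tumor_depth=15,
        tumor_alt_reads=4, vaf=0.25, mean_base_quality=30.0, indel_pvalue=None,
    )
    base.update(overrides)
    return RawCall(**base)


class TestThresholdRules:
    def test_clean_snv_is_retained(self):
        d = apply_threshold_filters(make_call(), EMPTY_PANEL, NO_MASK)
        assert d.retained and d.failed_rules == []

    @pytest.mark.parametrize(
        "overrides,expected",
        [
            ({"vaf": 0.08}, ["VAF"]),  # "not less than 10%"
            ({"vaf": 0.10}, []),  # boundary passes
            ({"mean_base_quality": 19.9}, ["BQ"]),
            ({"mean_base_quality": 20.0}, []),  # ">= 20"
            ({"normal_depth": 14}, ["DEPTH_NORMAL"]),  # "over 14" is strict
            ({"normal_depth": 15}, []),
            ({"tumor_depth": 8}, ["DEPTH_TUMOR"]),  # "over 8" is strict
            ({"tumor_depth": 9}, []),
        ],
    )
    def test_snv_rules(self, overrides, expected):
        d = apply_threshold_filters(make_call(**overrides), EMPTY_PANEL, NO_MASK)
        assert d.failed_rules == expected

    @pytest.mark.parametrize(
        "overrides,expected",
        [
            ({"tumor_depth": 10}, ["INDEL_DEPTH"]),  # "over 10" is strict
            ({"tumor_depth": 11}, []),
            ({"indel_pvalue": 0.002}, ["INDEL_P"]),  # "<= 0.001"
            ({"indel_pvalue": 0.001}, []),
        ],
    )
    def test_indel_rules(self, overrides, expected):
        base = dict(ref_allele="CAG", alt_allele="C", variant_type="DEL",
                    callers=frozenset({CALLER_B, CALLER_C}), passed_primary=False,
                    indel_pvalue=0.0005)
        base.update(overrides)
        d = apply_threshold_filters(make_call(**base), EMPTY_PANEL, NO_MASK)
        assert d.failed_rules == expected

    def test_indel_pvalue_only_checked_when_caller_c_called(self):
        call = make_call(ref_allele="CAG", alt_allele="C", variant_type="DEL",
                         callers=frozenset({CALLER_B}), indel_pvalue=None)
        d = apply_threshold_filters(call, EMPTY_PANEL, NO_MASK)
        assert "INDEL_P" not in d.failed_rules

    def test_failures_are_enumerated_not_short_circuited(self):
        call = make_call(vaf=0.05, mean_base_quality=10, normal_depth=5,
                         tumor_depth=5)
        d = apply_threshold_filters(call, EMPTY_PANEL, NO_MASK)
        assert d.failed_rules == ["VAF", "BQ", "DEPTH_NORMAL", "DEPTH_TUMOR"]

    def test_panel_membership_fails_pon(self):
        panel = PanelOfNormals({("chr1", 1000, "T")}, n_normals=3)
        d = apply_threshold_filters(make_call(), panel, NO_MASK)
        assert d.failed_rules == ["PON"]

    def test_mask_overlap_uses_full_ref_footprint(self):
        trees = mask_trees({"chr1": [(1004, 1050)]})  # 0-based half-open
        snv = make_call(position=1000)
        assert apply_threshold_filters(snv, EMPTY_PANEL, trees).retained
        deletion = make_call(position=1000, ref_allele="C" + "A" * 9,
                             alt_allele="C", variant_type="DEL",
                             callers=frozenset({CALLER_B, CALLER_C}),
                             indel_pvalue=1e-4)
        d = apply_threshold_filters(deletion, EMPTY_PANEL, trees)
        assert d.failed_rules == ["MASK"]

    def test_snv_with_indel_pvalue_is_schema_violation(self):
        with pytest.raises(InputError):
            apply_threshold_filters(make_call(indel_pvalue=0.5), EMPTY_PANEL,
                                    NO_MASK)


class TestConsensus:
    def test_snv_needs_primary_caller_pass(self):
        assert caller_consensus_ok(make_call())
        assert not caller_consensus_ok(make_call(passed_primary=False))
        assert not caller_consensus_ok(
            make_call(callers=frozenset({CALLER_B}), passed_primary=False))

    def test_indel_needs_both_indel_callers(self):
        indel = dict(ref_allele="CA", alt_allele="C", variant_type="DEL",
                     passed_primary=False, indel_pvalue=1e-4)
        assert caller_consensus_ok(
            make_call(callers=frozenset({CALLER_B, CALLER_C}), **indel))
        assert not caller_consensus_ok(
            make_call(callers=frozenset({CALLER_B}), **indel))

    def test_merge_unions_provenance_and_prioritizes_evidence(self):
        a = CallRecord("chr1", 100, "C", "T", passed=True,
                       info={"NDP": 30, "TDP": 20, "TAD": 5, "VAF": 0.25,
                             "MBQ": 35.0})
        b = CallRecord("chr1", 100, "C", "T", passed=True,
                       info={"NDP": 28, "TDP": 22, "TAD": 6, "VAF": 0.27,
                             "MBQ": 31.0})
        merged = consensus_merge({CALLER_A: [a], CALLER_B: [b]}, "s1")
        assert len(merged) == 1
        call = merged[0]
        assert call.callers == frozenset({CALLER_A, CALLER_B})
        assert call.passed_primary
        assert call.normal_depth == 30 and call.vaf == 0.25  # from caller A

    def test_merge_single_caller(self):
        b = CallRecord("chr1", 200, "G", "A", info={"VAF": 0.3})
        merged = consensus_merge({CALLER_B: [b]}, "s1")
        assert merged[0].callers == frozenset({CALLER_B})
        assert not merged[0].passed_primary

    def test_merged_indel_carries_caller_c_pvalue(self):
        b = CallRecord("chr1", 300, "GAT", "G",
                       info={"TDP": 20, "VAF": 0.3, "MBQ": 30.0})
        c = CallRecord("chr1", 300, "GAT", "G",
                       info={"TDP": 21, "VAF": 0.28, "MBQ": 29.0, "VP": 2e-4})
        merged = consensus_merge({CALLER_B: [b], CALLER_C: [c]}, "s1")
        call = merged[0]
        assert call.indel_pvalue == pytest.approx(2e-4)
        assert call.tumor_depth == 20  # evidence from B (higher priority)

    def test_merge_rejects_conflicting_refs(self):
        a = CallRecord("chr1", 100, "C", "T")
        b = CallRecord("chr1", 100, "G", "T")
        with pytest.raises(InputError, match="conflicting"):
            consensus_merge({CALLER_A: [a], CALLER_B: [b]}, "s1")

    def test_snv_called_by_b_only_is_consensus_filtered(self):
        call = make_call(callers=frozenset({CALLER_B}), passed_primary=False)
        res = filter_sample([call], EMPTY_PANEL, NO_MASK)
        assert res.retained == []
        assert res.decisions[call.key].failed_rules == ["CALLER_CONSENSUS"]


class TestPanel:
    def _write_normals(self, tmp_path, site_lists):
        contigs = {"chr1": 10_000}
        paths = []
        for i, sites in enumerate(site_lists):
            recs = [CallRecord("chr1", pos, ref, alt) for pos, ref, alt in sites]
            p = tmp_path / f"n{i}.vcf"
            write_vcf(p, recs, contigs)
            paths.append(p)
        return paths

    def test_site_in_enough_normals_enters_panel(self, tmp_path):
        paths = self._write_normals(
            tmp_path, [[(100, "A", "T")], [(100, "A", "T")], [(100, "A", "T")]])
        panel = build_normal_panel(paths, min_supporting_normals=2)
        assert ("chr1", 100, "T") in panel

    def test_rare_site_stays_out(self, tmp_path):
        paths = self._write_normals(
            tmp_path, [[(100, "A", "T")], [(200, "C", "G")], [(300, "G", "A")]])
        panel = build_normal_panel(paths, min_supporting_normals=2)
        assert ("chr1", 100, "T") not in panel
        assert len(panel.background_sites) == 0

    def test_contradictory_refs_raise(self, tmp_path):
        paths = self._write_normals(
            tmp_path, [[(100, "A", "T")], [(100, "C", "T")]])
        with pytest.raises(InputError, match="chr1:100"):
            build_normal_panel(paths)

    def test_no_normals_raises(self):
        with pytest.raises(InputError):
            build_normal_panel([])

    def test_panel_serializes_to_sites_only_vcf(self, tmp_path):
        panel = PanelOfNormals({("chr1", 100, "T"), ("chr1", 250, "G")}, 3)
        path = tmp_path / "pon.vcf"
        write_panel_vcf(panel, path, {"chr1": 10_000},
                        reference_lookup={"chr1": "A" * 10_000})
        from somacohort.vcfio import read_vcf

        back = {(r.chromosome, r.position, r.alt_allele) for r in read_vcf(path)}
        assert back == panel.background_sites

    def test_truth_artifact_sites_all_enter_panel(self, small_cohort):
        files = small_cohort["files"]
        panel = build_normal_panel(sorted(files.normal_vcfs.values()),
                                   min_supporting_normals=2)
        for chrom, pos, _ref, alt in files.artifact_sites:
            assert (chrom, pos, alt) in panel


def _random_calls(rng, n=1000):
    calls = []
    for i in range(n):
        is_snv = rng.random() < 0.7
        caller_pool = [CALLER_A, CALLER_B] if is_snv else [CALLER_B, CALLER_C]
        callers = frozenset(
            c for c in caller_pool if rng.random() < 0.8) or frozenset(
            [caller_pool[0]])
        vt = "SNV" if is_snv else ("DEL" if rng.random() < 0.5 else "INS")
        ref = "C" if vt != "DEL" else "C" + "A" * int(rng.integers(1, 6))
        alt = "T" if vt == "SNV" else ("C" if vt == "DEL"
                                       else "C" + "G" * int(rng.integers(1, 4)))
        tdp = int(rng.integers(1, 40))
        calls.append(RawCall(
            sample_id="s", chromosome="chr1",
            position=int(rng.integers(1, 20_000)),
            ref_allele=ref, alt_allele=alt, variant_type=vt, callers=callers,
            passed_primary=bool(rng.random() < 0.8),
            normal_depth=int(rng.integers(1, 40)), tumor_depth=tdp,
            tumor_alt_reads=min(tdp, int(rng.integers(0, 20))),
            vaf=float(rng.uniform(0, 0.6)),
            mean_base_quality=float(rng.uniform(5, 40)),
            indel_pvalue=None if vt == "SNV" or CALLER_C not in callers
            else float(rng.uniform(0, 0.01)),
        ))
    return calls


def test_filter_equals_rule_by_rule_oracle():
    """End-to-end decision matches a literal independent re-implementation."""
    rng = np.random.default_rng(77)
    calls = _random_calls(rng, 1000)
    panel = PanelOfNormals(
        {("chr1", int(p), a) for p, a in
         zip(rng.integers(1, 20_000, 300), rng.choice(list("ACGT"), 300))}, 5)
    mask_iv = {"chr1": [(int(s), int(s) + int(w)) for s, w in
                        zip(rng.integers(0, 20_000, 40),
                            rng.integers(20, 200, 40))]}
    trees = mask_trees(mask_iv)
    thresholds = FilterThresholds()
    res = filter_sample(calls, panel, trees, thresholds)
    got = {id(c) for c in res.retained}
    for call in calls:
        expect = filter_oracle_retained(call, panel.background_sites, mask_iv,
                                        thresholds)
        assert (id(call) in got) == expect


def test_raising_thresholds_never_increases_retention():
    rng = np.random.default_rng(3)
    calls = _random_calls(rng, 400)
    base = FilterThresholds()
    n_base = len(filter_sample(calls, EMPTY_PANEL, NO_MASK, base).retained)
    for fld, delta in [("min_vaf", 0.05), ("min_bq", 5), ("min_normal_depth", 5),
                       ("min_tumor_depth", 5), ("min_indel_depth", 5)]:
        t = dataclasses.replace(base, **{fld: getattr(base, fld) + delta})
        assert len(filter_sample(calls, EMPTY_PANEL, NO_MASK, t).retained) <= n_base
    tighter_p = dataclasses.replace(base, max_indel_p=base.max_indel_p / 10)
    assert len(filter_sample(calls, EMPTY_PANEL, NO_MASK, tighter_p).retained) \
        <= n_base


def test_no_final_variant_is_in_the_panel(small_cohort):
    panel = small_cohort["panel"]
    for res in small_cohort["results"].values():
        for call in res.retained:
            assert (call.chromosome, call.position, call.alt_allele) not in panel


def test_cohort_filter_f1_on_default_noise(small_cohort):
    perf = evaluate_against_truth(small_cohort["results"],
                                  small_cohort["truth"].keys_by_sample())
    assert perf["f1"] >= 0.95
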