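"""Tukey thresholding, outlier calls, consensus, curation-tier helpers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import panoutlier as po
from panoutlier.cohorts import CohortSpec
from panoutlier.compendium import FocusProfile
from panoutlier.outliers import (
    OutlierCall,
    consensus_pan_disease,
    highly_expressed_genes,
    qc_fail_filter,
    tukey_threshold,
)


class TestTukeyThreshold:
    def test_hand_interpolated_example(self):
        # positions 1+0.75*7 and 1+0.25*7 on sorted 1..8
        q75, iqr, thr = tukey_threshold([1, 2, 3, 4, 5, 6, 7, 8])
        assert (q75, iqr, thr) == (6.25, 3.5, 11.5)

    def test_constant_vector(self):
        assert tukey_threshold([5, 5, 5, 5]) == (5.0, 0.0, 5.0)

    def test_zero_multiplier_degenerates_to_q75(self):
        q75, iqr, thr = tukey_threshold([3, 1, 4, 1, 5], iqr_multiplier=0.0)
        assert thr == q75

    def test_order_invariance(self):
        assert tukey_threshold([8, 1, 5, 2, 7, 3, 6, 4]) == tukey_threshold(range(1, 9))

    @pytest.mark.parametrize("bad", [[], [1.0], [1.0, np.inf]])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            tukey_threshold(bad)


def _cohort_compendium(cohort_values, focus_value, gene="G1"):
    """Single-gene compendium: focus sample F plus cohort members."""
    members = [f"C{i}" for i in range(len(cohort_values))]
    row = {m: v for m, v in zip(members, cohort_values)}
    row["F"] = focus_value
    # pad with a second gene so profiles are non-degenerate
    values = pd.DataFrame([row, {k: 1.0 for k in row}], index=[gene, "G2"])
    c = po.ExpressionCompendium(values)
    spec = CohortSpec("pan_cancer", frozenset(members), "test")
    profile = FocusProfile("F", c.values["F"])
    return c, spec, profile


PARAMS = po.Parameters(min_cohort_size=2)


class TestCallOutliers:
    @pytest.mark.parametrize(
        "focus_value,expected",
        [(12.0, True), (11.5, False), (11.5000001, True)],
    )
    def test_strict_exceedance_of_threshold(self, focus_value, expected):
        c, spec, profile = _cohort_compendium(list(range(1, 9)), focus_value)
        calls = {x.gene: x for x in po.call_outliers(profile, spec, c, ["G1"], PARAMS)}
        assert calls["G1"].threshold == 11.5
        assert calls["G1"].is_outlier is expected

    def test_constant_cohort_threshold_equals_value(self):
        c, spec, profile = _cohort_compendium([5.0] * 4, 5.1)
        calls = {x.gene: x for x in po.call_outliers(profile, spec, c, ["G1"], PARAMS)}
        assert calls["G1"].threshold == 5.0 and calls["G1"].is_outlier

    def test_calls_sorted_by_exceedance_margin(self, small_compendium):
        c, _ = small_compendium
        focus = c.samples[0]
        spec = po.build_predefined_cohorts(focus, c, PARAMS)["pan_cancer"]
        calls = po.call_outliers(c.focus_profile(focus), spec, c, None, PARAMS)
        margins = [x.margin for x in calls]
        assert margins == sorted(margins, reverse=True)
        assert len(calls) == c.n_genes

    def test_unusable_cohort_returns_empty(self, small_compendium):
        c, _ = small_compendium
        focus = c.samples[0]
        spec = CohortSpec("same_disease", frozenset(c.samples[1:3]), "tiny")
        assert po.call_outliers(c.focus_profile(focus), spec, c, None, po.Parameters()) == []

    def test_focus_in_cohort_rejected(self, small_compendium):
        c, _ = small_compendium
        focus = c.samples[0]
        spec = CohortSpec("pan_cancer", frozenset(c.samples), "bad")
        with pytest.raises(ValueError, match="must not be a member"):
            po.call_outliers(c.focus_profile(focus), spec, c, None, PARAMS)

    def test_threshold_identity_holds(self, small_compendium):
        c, _ = small_compendium
        focus = c.samples[0]
        spec = po.build_predefined_cohorts(focus, c, PARAMS)["pan_cancer"]
        for call in po.call_outliers(c.focus_profile(focus), spec, c, None, PARAMS)[:50]:
            assert call.threshold == pytest.approx(call.q75 + 1.5 * call.iqr, abs=1e-9)
            assert call.iqr >= 0
            assert call.is_outlier == (call.focus_expression > call.threshold)

    def test_permutation_invariance_of_cohort_samples(self, small_compendium):
        c, _ = small_compendium
        focus = c.samples[0]
        spec = po.build_predefined_cohorts(focus, c, PARAMS)["pan_cancer"]
        calls_a = po.call_outliers(c.focus_profile(focus), spec, c, None, PARAMS)
        perm = list(np.random.default_rng(3).permutation(c.samples))
        c2 = c.subset_samples(perm)
        calls_b = po.call_outliers(c2.focus_profile(focus), spec, c2, None, PARAMS)
        assert calls_a == calls_b

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotonicity_in_focus_expression(self, seed):
        rng = np.random.default_rng(seed)
        cohort_values = rng.normal(5, 2, size=int(rng.integers(4, 30))).tolist()
        e2 = float(rng.normal(5, 3))
        e1 = e2 + float(rng.uniform(0.1, 3))
        _, iqr, thr = tukey_threshold(cohort_values)
        if e2 > thr:  # e2 outlier implies e1 outlier
            assert e1 > thr


class TestConsensus:
    def _calls(self, pattern):
        """pattern: mapping cohort -> gene is outlier (single gene 'G')."""
        return {
            name: [OutlierCall("G", name, 1, 1, 2.5, 3.0 if hit else 0.0, hit)]
            for name, hit in pattern.items()
        }

    def test_two_cohorts_make_consensus(self):
        calls = self._calls(
            {"same_disease": True, "top6_diseases": True, "first_degree": False,
             "first_second_degree": False}
        )
        consensus, single = consensus_pan_disease(calls, 2)
        assert consensus == {"G"} and single == set()

    def test_one_cohort_routes_to_single_tier(self):
        calls = self._calls(
            {"same_disease": False, "top6_diseases": False, "first_degree": True,
             "first_second_degree": False}
        )
        consensus, single = consensus_pan_disease(calls, 2)
        assert consensus == set() and single == {"G"}

    def test_zero_cohorts_neither(self):
        calls = self._calls({n: False for n in
                             ("same_disease", "top6_diseases", "first_degree",
                              "first_second_degree")})
        consensus, single = consensus_pan_disease(calls, 2)
        assert consensus == set() and single == set()

    def test_consensus_subset_of_union_and_disjoint_from_single(self, small_compendium):
        c, _ = small_compendium
        focus = c.samples[0]
        sim = po.compute_similarity(c, po.Parameters(similarity_percentile=0.85))
        cohorts = po.build_pan_disease_cohorts(focus, c, sim, PARAMS)
        per_cohort = {
            n: po.call_outliers(c.focus_profile(focus), s, c, None, PARAMS)
            for n, s in cohorts.items()
        }
        consensus, single = consensus_pan_disease(per_cohort, 2)
        union = set().union(*({x.gene for x in calls if x.is_outlier}
                              for calls in per_cohort.values()))
        assert consensus <= union
        assert not (consensus & single)


class TestCurationTiers:
    def test_highly_expressed_interpolated_cutoff(self):
        profile = pd.Series(
            np.arange(1.0, 101.0), index=[f"G{i:03d}" for i in range(100)]
        )
        # cutoff at position 1 + 0.95*99 = 95.05
        assert highly_expressed_genes(profile, 0.95) == {f"G{i:03d}" for i in range(95, 100)}

    def test_constant_profile_has_no_highly_expressed(self):
        profile = pd.Series(np.ones(50), index=[f"G{i}" for i in range(50)])
        assert highly_expressed_genes(profile, 0.95) == set()

    @pytest.mark.parametrize("value,kept", [(8.6, True), (8.5, False)])
    def test_qc_fail_cutoff_strict(self, value, kept):
        profile = FocusProfile(
            "F",
            pd.Series([value, 1.0, 2.0], index=["G1", "G2", "G3"]),
            qc_status="fail",
        )
        genes, p95 = qc_fail_filter(profile)
        assert ("G1" in genes) is kept
        assert p95 == pytest.approx(np.quantile([value, 1.0, 2.0], 0.95))

    def test_qc_pass_sample_rejected(self):
        profile = FocusProfile("F", pd.Series([1.0, 2.0], index=["G1", "G2"]), "pass")
        with pytest.raises(ValueError, match="qc_status"):
            qc_fail_filter(profile)
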