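"""Comparator-cohort construction: personalized, predefined, curated."""

import numpy as np
import pandas as pd
import pytest

import panoutlier as po
from panoutlier.cohorts import CohortSpec, normalize_disease
from panoutlier.similarity import SimilarityResult

from conftest import make_metadata


def _compendium_with_meta(n_genes=30, diseases=("ependymoma",) * 3 + ("glioma",) * 3,
                          ages=None, sources=None, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(len(diseases))]
    values = pd.DataFrame(
        rng.random((n_genes, len(samples))) * 10,
        index=[f"G{i}" for i in range(n_genes)],
        columns=samples,
    )
    meta = make_metadata(samples, list(diseases), ages=ages, sources=sources)
    return po.ExpressionCompendium(values, meta)


def _sim_for(c, entries, threshold):
    corr = pd.DataFrame(np.eye(c.n_samples), index=c.samples, columns=c.samples)
    for (a, b), rho in entries.items():
        corr.at[a, b] = rho
        corr.at[b, a] = rho
    return SimilarityResult(correlations=corr, threshold=threshold, method="override")


PARAMS = po.Parameters(min_cohort_size=2)


class TestPanDiseaseCohorts:
    def test_cohort_rules_on_crafted_similarity(self):
        c = _compendium_with_meta()
        # S0 focus (ependymoma).  S1 ependymoma neighbor; S3 glioma is S1's
        # neighbor but not S0's; top-6 covers everyone.
        sim = _sim_for(
            c,
            {("S0", "S1"): 0.95, ("S1", "S3"): 0.95, ("S0", "S3"): 0.5},
            threshold=0.9,
        )
        cohorts = po.build_pan_disease_cohorts("S0", c, sim, PARAMS)
        assert cohorts["same_disease"].members == {"S1", "S2"}
        assert cohorts["first_degree"].members == {"S1"}
        assert cohorts["first_second_degree"].members == {"S1", "S3"}
        # top-6 = all 5 others -> both diseases -> every other sample
        assert cohorts["top6_diseases"].members == {"S1", "S2", "S3", "S4", "S5"}

    def test_top6_single_disease_restricts_cohort(self):
        c = _compendium_with_meta()
        params = po.Parameters(min_cohort_size=2, top_k_correlated=2)
        sim = _sim_for(c, {("S0", "S1"): 0.99, ("S0", "S2"): 0.98}, threshold=0.9)
        cohorts = po.build_pan_disease_cohorts("S0", c, sim, params)
        assert cohorts["top6_diseases"].members == {"S1", "S2"}

    def test_focus_disease_absent_gives_empty_unusable_cohort(self):
        c = _compendium_with_meta(diseases=("DSRCT",) + ("glioma",) * 5)
        sim = _sim_for(c, {}, threshold=0.9)
        cohorts = po.build_pan_disease_cohorts("S0", c, sim, PARAMS)
        assert cohorts["same_disease"].members == frozenset()
        assert not cohorts["same_disease"].usable(PARAMS.min_cohort_size)

    def test_second_degree_always_superset_of_first(self, small_compendium):
        c, _ = small_compendium
        sim = po.compute_similarity(c, po.Parameters(similarity_percentile=0.9))
        for focus in c.samples[:5]:
            cohorts = po.build_pan_disease_cohorts(focus, c, sim, PARAMS)
            assert cohorts["first_second_degree"].members >= cohorts["first_degree"].members
            for spec in cohorts.values():
                assert focus not in spec.members

    def test_disease_matching_normalizes_case_and_whitespace(self):
        c = _compendium_with_meta(diseases=("Ependymoma",) + ("  ependymoma ",) * 2 + ("glioma",) * 3)
        sim = _sim_for(c, {}, threshold=0.9)
        cohorts = po.build_pan_disease_cohorts("S0", c, sim, PARAMS)
        assert cohorts["same_disease"].members == {"S1", "S2"}


class TestPredefinedCohorts:
    def _compendium(self):
        return _compendium_with_meta(
            diseases=("ependymoma",) * 6,
            ages=[29.0, 30.0, 12.0, 45.0, None, 7.0],
            sources=["tcga", "tcga", "institution", "other", "institution", "tcga"],
        )

    def test_age_boundary_strict(self):
        c = self._compendium()
        cohorts = po.build_predefined_cohorts("S3", c, PARAMS)
        assert "S0" in cohorts["pediatric"].members  # age 29
        assert "S1" not in cohorts["pediatric"].members  # age 30
        assert "S4" not in cohorts["pediatric"].members  # age missing

    def test_source_strata_disjoint_and_pan_cancer_complete(self):
        c = self._compendium()
        cohorts = po.build_predefined_cohorts("S3", c, PARAMS)
        assert cohorts["tcga_only"].members & cohorts["institution"].members == frozenset()
        assert cohorts["pan_cancer"].members == set(c.samples) - {"S3"}
        for spec in cohorts.values():
            assert "S3" not in spec.members

    def test_pediatric_and_complement_cover_aged_samples(self):
        c = self._compendium()
        cohorts = po.build_predefined_cohorts("S3", c, PARAMS)
        aged = {s for s in c.samples if s != "S3" and c.metadata[s].age_at_diagnosis is not None}
        adult = {s for s in aged if c.metadata[s].age_at_diagnosis >= 30}
        assert cohorts["pediatric"].members | adult == aged


class TestCuratedCohort:
    def test_union_of_curated_diseases(self):
        c = _compendium_with_meta(
            diseases=("undifferentiated sarcoma", "synovial sarcoma", "synovial sarcoma",
                      "leiomyosarcoma", "glioma", "glioma")
        )
        spec = po.substitute_curated_cohort("S0", c, ["Synovial Sarcoma", "leiomyosarcoma"])
        assert spec.members == {"S1", "S2", "S3"}
        assert spec.curated_flag and spec.name == "curated"

    def test_empty_curated_set_rejected(self, small_compendium):
        c, _ = small_compendium
        with pytest.raises(ValueError, match="empty"):
            po.substitute_curated_cohort(c.samples[0], c, [])

    def test_unmatched_curated_set_rejected(self, small_compendium):
        c, _ = small_compendium
        with pytest.raises(ValueError, match="no compendium samples"):
            po.substitute_curated_cohort(c.samples[0], c, ["no such disease"])


class TestCohortSpec:
    def test_name_must_be_known(self):
        with pytest.raises(ValueError, match="cohort name"):
            CohortSpec("bogus", frozenset(), "x")

    def test_curated_flag_tied_to_name(self):
        with pytest.raises(ValueError, match="curated_flag"):
            CohortSpec("pan_cancer", frozenset(), "x", curated_flag=True)

    def test_growth_monotonicity_when_appending_unrelated_disease(self):
        c = _compendium_with_meta()
        sim = _sim_for(c, {("S0", "S1"): 0.95}, threshold=0.9)
        before = po.build_pan_disease_cohorts("S0", c, sim, PARAMS)
        # append two samples of an unrelated disease, uncorrelated to all
        rng = np.random.default_rng(5)
        extra = pd.DataFrame(
            rng.random((c.n_genes, 2)) * 10, index=c.genes, columns=["X0", "X1"]
        )
        values = pd.concat([c.values, extra], axis=1)
        meta = list(c.metadata.values()) + make_metadata(["X0", "X1"], ["melanoma"] * 2)
        c2 = po.ExpressionCompendium(values, meta)
        corr2 = sim.correlations.reindex(index=c2.samples, columns=c2.samples, fill_value=0.0)
        for s in c2.samples:
            corr2.at[s, s] = 1.0
        sim2 = SimilarityResult(corr2, sim.threshold, "override")
        after = po.build_pan_disease_cohorts("S0", c2, sim2, PARAMS)
        for name in ("same_disease", "first_degree", "first_second_degree"):
            assert after[name].members >= before[name].members


def test_normalize_disease():
    assert normalize_disease("  Synovial   Sarcoma ") == "synovial sarcoma"
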