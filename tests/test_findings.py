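"""Finding classification, druggability, pathway overlap, report assembly."""

import itertools
import json

import numpy as np
import pytest

import panoutlier as po
from panoutlier.cohorts import COHORT_NAMES
from panoutlier.findings import (
    CurationInputs,
    annotate_pathway_support,
    assemble_report,
    classify_findings,
    druggable_filter,
    hypergeometric_overlap_p,
    pathway_overlap_test,
    write_report,
)


class TestClassification:
    def test_both_pipelines(self):
        found = classify_findings("F", {"A", "B"}, {"B", "C"})
        types = {f.gene: f.finding_type for f in found}
        assert types == {"A": "pan_cancer_only", "B": "both", "C": "pan_disease_only"}

    def test_single_cohort_gene_becomes_curated(self):
        found = classify_findings(
            "F", set(), set(), CurationInputs(single_cohort={"KIT"})
        )
        (f,) = found
        assert f.finding_type == "curated" and f.curation_subtype == "single_cohort"

    def test_curation_never_overrides_automated(self):
        found = classify_findings(
            "F", {"A"}, set(), CurationInputs(single_cohort={"A"}, highly_expressed={"A"})
        )
        (f,) = found
        assert f.finding_type == "pan_cancer_only"

    def test_each_gene_gets_exactly_one_type(self):
        found = classify_findings(
            "F",
            {"A", "B"},
            {"B", "C"},
            CurationInputs(
                curated_consensus={"D"},
                single_cohort={"D", "E"},
                highly_expressed={"E", "F1"},
                mutation_implicated={"A"},
            ),
        )
        genes = [f.gene for f in found]
        assert len(genes) == len(set(genes))
        # priority: curated_cohort beats single_cohort for D
        by_gene = {f.gene: f for f in found}
        assert by_gene["D"].curation_subtype == "curated_cohort"
        assert by_gene["E"].curation_subtype == "single_cohort"
        assert by_gene["F1"].curation_subtype == "highly_expressed"

    def test_types_partition_counts(self):
        found = classify_findings(
            "F", {"A", "B"}, {"B"}, CurationInputs(single_cohort={"C"})
        )
        counts = {t: 0 for t in ("pan_cancer_only", "pan_disease_only", "both", "curated")}
        for f in found:
            counts[f.finding_type] += 1
        assert sum(counts.values()) == len(found) == 3


class TestDruggable:
    def _findings(self, genes):
        return classify_findings("F", set(genes), set())

    def test_flag_set_for_listed_genes(self):
        found = druggable_filter(self._findings(["KIT", "XYZ"]), ["KIT", "ERBB2"])
        by_gene = {f.gene: f.druggable for f in found}
        assert by_gene == {"KIT": True, "XYZ": False}

    def test_case_normalized_match_warns(self, caplog):
        import logging

        logging.getLogger("panoutlier").setLevel(logging.WARNING)
        with caplog.at_level("WARNING", logger="panoutlier.findings"):
            found = druggable_filter(self._findings(["kit"]), ["KIT"])
        assert found[0].druggable
        assert any("case" in rec.message for rec in caplog.records)

    def test_empty_list_all_false_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="panoutlier.findings"):
            found = druggable_filter(self._findings(["KIT"]), [])
        assert not found[0].druggable
        assert any("empty" in rec.message for rec in caplog.records)


class TestHypergeometric:
    def test_documented_example(self):
        # universe 10, set 5, query 4, overlap 4 -> C(5,4)/C(10,4) = 5/210
        assert hypergeometric_overlap_p(10, 5, 4, 4) == pytest.approx(5 / 210)

    def test_zero_query_gives_p_one(self):
        assert hypergeometric_overlap_p(10, 5, 0, 0) == 1.0

    def test_overlap_beyond_possible_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap_p(10, 3, 4, 4)


class TestOverlapTest:
    def _collection(self):
        return po.GeneSetCollection(
            sets={
                "HIT": frozenset({"A", "B", "C"}),
                "MISS": frozenset({"X", "Y", "Z"}),
            }
        )

    def test_sorted_by_p_and_bh_monotone(self):
        universe = set("ABCDEFGHXYZ")
        results = pathway_overlap_test({"A", "B", "C"}, self._collection(), universe)
        assert [r.set_name for r in results] == ["HIT", "MISS"]
        for r in results:
            assert r.p_adjusted >= r.p_value
            assert 0 < r.p_value <= 1

    def test_identical_set_has_smallest_p(self):
        universe = {f"G{i}" for i in range(12)} | set("ABC")
        coll = po.GeneSetCollection(
            sets={"EXACT": frozenset("ABC"), "OTHER": frozenset({"G0", "G1", "G2"})}
        )
        results = pathway_overlap_test(set("ABC"), coll, universe)
        assert results[0].set_name == "EXACT"

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            pathway_overlap_test({"Q"}, self._collection(), {"A"})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            pathway_overlap_test(set(), self._collection(), set())


class TestReport:
    def test_empty_report_is_valid_and_writable(self, tmp_path):
        report = assemble_report("F", [], [], po.Parameters())
        assert report["n_findings"] == 0
        paths = write_report(report, tmp_path)
        loaded = json.loads(paths["json"].read_text())
        assert loaded["findings"] == []
        assert paths["tsv"].read_text().startswith("focus\tgene")

    def test_evidence_cohort_names_are_schema_closed(self, small_compendium):
        c, truth = small_compendium
        focus = c.samples[0]
        planted, truth = po.plant_outliers(c, focus, truth.druggable_genes[:3], 3.0, truth)
        spec = po.build_predefined_cohorts(focus, planted, po.Parameters())["pan_cancer"]
        calls = po.call_outliers(planted.focus_profile(focus), spec, planted)
        evidence = {}
        outliers = set()
        for call in calls:
            if call.is_outlier:
                evidence.setdefault(call.gene, []).append(call)
                outliers.add(call.gene)
        found = classify_findings(focus, outliers, set(), evidence=evidence)
        report = assemble_report(focus, found, [], po.Parameters())
        for f in report["findings"]:
            for e in f["evidence"]:
                assert e["cohort"] in COHORT_NAMES

    def test_finding_type_counts_sum_to_total(self):
        found = classify_findings(
            "F", {"A", "B"}, {"B", "C"}, CurationInputs(single_cohort={"D"})
        )
        report = assemble_report("F", found, [], po.Parameters())
        assert sum(report["finding_type_counts"].values()) == report["n_findings"] == 4
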