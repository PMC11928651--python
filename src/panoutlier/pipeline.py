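"""End-to-end orchestration: filters -> similarity -> cohorts -> outliers ->
findings -> cohort comparison, driven by a YAML run configuration.

The pipeline is deterministic given its inputs and configuration: reports
are written as canonical JSON (sorted keys, no timestamps), so two runs on
the same inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from .cohorts import (
    PAN_DISEASE_COHORTS,
    PREDEFINED_COHORTS,
    build_pan_disease_cohorts,
    build_predefined_cohorts,
    substitute_curated_cohort,
)
from .comparison import added_findings, compare_cohorts, exclusive_intersections
from .compendium import (
    ExpressionCompendium,
    load_compendium,
    read_gene_list,
    read_gmt,
    validate_compendium,
)
from .filters import pan_cancer_gene_space
from .findings import (
    CurationInputs,
    annotate_pathway_support,
    assemble_report,
    classify_findings,
    druggable_filter,
    pathway_overlap_test,
    write_report,
)
from .outliers import (
    call_outliers,
    consensus_pan_disease,
    highly_expressed_genes,
    outlier_gene_set,
    qc_fail_filter,
)
from .params import Parameters
from .similarity import compute_similarity

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, parameters and switches for one pipeline run."""

    matrix: Path
    metadata: Path
    focus: str
    out_dir: Path
    druggable_list: Optional[Path] = None
    gene_sets: Optional[Path] = None
    mutation_implicated: Optional[Path] = None
    curated_diseases: List[str] = field(default_factory=list)
    params: Parameters = field(default_factory=Parameters)
    cohort_sets: str = "all"  # "personalized" | "predefined" | "all"
    seed: int = 0

    def __post_init__(self) -> None:
        self.matrix = Path(self.matrix)
        self.metadata = Path(self.metadata)
        self.out_dir = Path(self.out_dir)
        for attr in ("druggable_list", "gene_sets", "mutation_implicated"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, Path(v))
        if self.cohort_sets not in ("personalized", "predefined", "all"):
            raise ValueError(f"cohort_sets must be personalized|predefined|all, got {self.cohort_sets!r}")
        for attr in ("matrix", "metadata"):
            p = getattr(self, attr)
            if not p.exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        params = Parameters.from_dict(data.pop("params", {}) or {})
        data.update(overrides)
        data["params"] = params
        return cls(**data)


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the full comparative analysis for one focus sample.

    Stages: load/validate -> gene filters -> similarity -> cohorts (with
    curated substitution when the same-disease cohort is unusable and a
    curated disease set is configured) -> per-cohort Tukey calls ->
    consensus + curation tiers -> findings classification, druggability and
    pathway support -> predefined-cohort comparison -> report files.
    """
    stage = "load"
    try:
        c = load_compendium(config.matrix, config.metadata)
        if config.focus not in set(c.samples):
            raise KeyError(f"focus sample {config.focus!r} not in compendium")
        issues = validate_compendium(c)
        for issue in issues:
            logger.warning("compendium issue: %s", issue)
        logger.info(
            "compendium: %d genes x %d samples; focus=%s", c.n_genes, c.n_samples, config.focus
        )
        params = config.params
        focus = config.focus
        profile = c.focus_profile(focus)

        stage = "gene_filters"
        space = pan_cancer_gene_space(c, params)
        logger.info(
            "gene filters: %d retained, %d zero-dropped, %d variance-dropped",
            len(space.retained),
            len(space.dropped_zero),
            len(space.dropped_variance),
        )

        stage = "similarity"
        sim = compute_similarity(c, params, space.retained or None)
        logger.info("similarity threshold %.4f (%s)", sim.threshold, sim.method)

        stage = "cohorts"
        pan_disease = build_pan_disease_cohorts(focus, c, sim, params)
        predefined = build_predefined_cohorts(focus, c, params)
        curated_used = False
        if (
            not pan_disease["same_disease"].usable(params.min_cohort_size)
            and config.curated_diseases
        ):
            curated = substitute_curated_cohort(focus, c, config.curated_diseases)
            pan_disease = dict(pan_disease)
            pan_disease["same_disease"] = curated
            curated_used = True
            logger.info("same-disease cohort replaced by curated cohort (%d members)", curated.size)
        cohort_summaries = [
            {
                "name": spec.name,
                "size": spec.size,
                "usable": spec.usable(params.min_cohort_size),
                "curated": spec.curated_flag,
                "provenance": spec.provenance,
            }
            for spec in list(pan_disease.values()) + list(predefined.values())
        ]

        stage = "qc_gate"
        candidate_genes: Optional[set] = None
        if profile.qc_status == "fail":
            candidate_genes, p95 = qc_fail_filter(profile, params=params)
            logger.warning(
                "focus failed QC: candidates restricted to expression > %.2f "
                "(profile 95th percentile = %.2f); %d genes remain",
                params.qc_fail_expression_cutoff,
                p95,
                len(candidate_genes),
            )

        stage = "outliers"
        pan_cancer_calls = call_outliers(
            profile, predefined["pan_cancer"], c, space.retained, params
        )
        pan_cancer_set = outlier_gene_set(pan_cancer_calls)
        per_cohort_calls = {
            name: call_outliers(profile, spec, c, None, params)
            for name, spec in pan_disease.items()
        }
        consensus, single = consensus_pan_disease(per_cohort_calls, params.consensus_min_cohorts)
        if curated_used:
            # consensus reached only with the curated substitute cohort is a
            # curation-derived finding, not an automated one
            canonical_calls = {
                n: calls for n, calls in per_cohort_calls.items() if n != "same_disease"
            }
            canonical_consensus, canonical_single = consensus_pan_disease(
                canonical_calls, params.consensus_min_cohorts
            )
            curated_only = consensus - canonical_consensus
            consensus, single = canonical_consensus, canonical_single
        else:
            curated_only = set()
        if candidate_genes is not None:
            pan_cancer_set &= candidate_genes
            consensus &= candidate_genes
            single &= candidate_genes
            curated_only &= candidate_genes

        stage = "curation_tiers"
        high = highly_expressed_genes(profile, params.highly_expressed_percentile)
        mutation = (
            set(read_gene_list(config.mutation_implicated))
            if config.mutation_implicated
            else set()
        )
        # The full 95th-percentile list is an analyst review tier, not an
        # automated finding source; only mutation-implicated members of it
        # are promoted to curated findings.  The list itself is emitted with
        # the report for review.
        curation = CurationInputs(
            curated_consensus=curated_only,
            single_cohort=single,
            highly_expressed=set(),
            mutation_implicated=mutation & high,
        )

        stage = "findings"
        evidence: Dict[str, list] = {}
        for calls in [pan_cancer_calls] + list(per_cohort_calls.values()):
            for call in calls:
                if call.is_outlier:
                    evidence.setdefault(call.gene, []).append(call)
        found = classify_findings(focus, pan_cancer_set, consensus, curation, evidence)
        druggable = read_gene_list(config.druggable_list) if config.druggable_list else []
        if not config.druggable_list:
            logger.warning("no druggable gene list configured; all findings druggable=false")
        found = druggable_filter(found, druggable)

        stage = "pathway_overlap"
        overlap_results = []
        if config.gene_sets:
            collection = read_gmt(config.gene_sets)
            universe = set(c.genes)
            query = (pan_cancer_set | consensus) & universe
            overlap_results = pathway_overlap_test(query, collection, universe)
            found = annotate_pathway_support(
                found, overlap_results, collection, params.pathway_fdr_cutoff
            )

        stage = "comparison"
        druggable_space = [g for g in c.genes if g in set(druggable)] or space.retained
        comparison = compare_cohorts(
            [focus], c, list(PREDEFINED_COHORTS), params, druggable_space, sim
        )
        personalized_genes = {
            focus: {g for g in (consensus | curated_only) if g in set(druggable_space)}
        }
        predefined_genes = {
            focus: {g for (f, g) in set().union(*comparison.per_cohort_outliers.values())}
            if comparison.per_cohort_outliers
            else set()
        }
        added = added_findings(personalized_genes, predefined_genes)

        stage = "report"
        report = assemble_report(
            focus,
            found,
            overlap_results,
            params,
            cohort_summaries,
            {
                "threshold": sim.threshold,
                "method": sim.method,
                "n_first_degree": pan_disease["first_degree"].size
                if "first_degree" in pan_disease
                else None,
            },
            qc_status=profile.qc_status,
        )
        review = high & set(druggable) if druggable else high
        report["highly_expressed_review"] = sorted(review)
        report["added_findings"] = added
        paths = write_report(report, config.out_dir)
        _write_comparison_tables(comparison, added, config.out_dir, focus)
        logger.info("wrote %s", paths["json"])
        return {
            "report": report,
            "paths": paths,
            "comparison": comparison,
            "added_findings": added,
        }
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def _write_comparison_tables(comparison, added: Dict, out_dir: Path, focus: str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for key in sorted(comparison.intersections):
        pairs = comparison.intersections[key]
        rows.append(
            {
                "cohorts": "&".join(key),
                "n_findings": len(pairs),
                "findings": ";".join(f"{f}:{g}" for f, g in sorted(pairs)),
            }
        )
    pd.DataFrame(rows, columns=["cohorts", "n_findings", "findings"]).to_csv(
        out_dir / f"intersections_{focus}.tsv", sep="\t", index=False
    )
    diag_rows = [
        {"gene": g, "cohort": name, **stats_d}
        for (g, name), stats_d in sorted(comparison.diagnostics.items())
    ]
    pd.DataFrame(
        diag_rows, columns=["gene", "cohort", "median", "q75", "iqr", "threshold"]
    ).to_csv(out_dir / f"diagnostics_{focus}.tsv", sep="\t", index=False)
    (out_dir / f"added_findings_{focus}.json").write_text(
        json.dumps(added, indent=2, sort_keys=True) + "\n"
    )
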