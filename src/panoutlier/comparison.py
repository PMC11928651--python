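"""Comparator-cohort impact experiments.

Which outliers does each cohort design detect?  This module repeats Tukey
outlier calling for a set of focus samples against several comparator
cohorts over a common (druggable) gene space, decomposes the detected
(focus, gene) findings into exclusive intersection cells (the UpSet view:
every finding is assigned to exactly one cohort-combination cell),
records per-(gene, cohort) distribution diagnostics (median, Q75, IQR,
threshold — the machine-checkable form of "median lower but threshold
higher"), quantifies how many findings personalized pan-disease cohorts add
over predefined ones, and re-runs the personalized analysis against two
compendium versions to classify per-gene finding-status transitions.

Accounting is per (focus, gene) pair throughout, so the same gene detected
in two patients counts twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .cohorts import (
    PAN_DISEASE_COHORTS,
    CohortSpec,
    build_pan_disease_cohorts,
    build_predefined_cohorts,
    normalize_disease,
)
from .compendium import ExpressionCompendium
from .filters import pan_cancer_gene_space
from .outliers import call_outliers, consensus_pan_disease, outlier_gene_set, tukey_threshold
from .params import Parameters
from .similarity import SimilarityResult, compute_similarity, top_k_correlated

logger = logging.getLogger(__name__)

Pair = Tuple[str, str]  # (focus sample, gene)


def exclusive_intersections(per_cohort: Mapping[str, Set]) -> Dict[Tuple[str, ...], Set]:
    """Decompose per-cohort detection sets into exclusive cells.

    Each element of the union is assigned to exactly one cell, keyed by the
    sorted tuple of cohort names that detected it.  Cells partition the
    union by construction.
    """
    union = set().union(*per_cohort.values()) if per_cohort else set()
    cells: Dict[Tuple[str, ...], Set] = {}
    for item in union:
        key = tuple(sorted(name for name, s in per_cohort.items() if item in s))
        cells.setdefault(key, set()).add(item)
    return cells


@dataclass
class ComparisonResult:
    per_cohort_outliers: Dict[str, Set[Pair]]
    intersections: Dict[Tuple[str, ...], Set[Pair]]
    diagnostics: Dict[Tuple[str, str], Dict[str, float]]  # (gene, cohort) -> stats
    unusable_cohorts: Dict[str, List[str]] = field(default_factory=dict)


def distribution_diagnostics(
    gene: str,
    cohorts: Mapping[str, CohortSpec],
    c: ExpressionCompendium,
    params: Optional[Parameters] = None,
) -> Dict[str, Dict[str, float]]:
    """Per-cohort {median, q75, iqr, threshold} for one gene."""
    params = params or Parameters()
    out: Dict[str, Dict[str, float]] = {}
    for name, spec in cohorts.items():
        values = c.values.loc[gene, sorted(spec.members)].to_numpy(dtype=float)
        if values.size < 2:
            logger.warning("cohort %s has <2 members; no diagnostics for %s", name, gene)
            continue
        q75, iqr, thr = tukey_threshold(values, params.iqr_multiplier, params.quartile_upper)
        out[name] = {
            "median": float(np.median(values)),
            "q75": q75,
            "iqr": iqr,
            "threshold": thr,
        }
    return out


def compare_cohorts(
    focus_set: Sequence[str],
    c: ExpressionCompendium,
    cohort_names: Sequence[str],
    params: Optional[Parameters] = None,
    gene_space: Optional[Sequence[str]] = None,
    sim: Optional[SimilarityResult] = None,
) -> ComparisonResult:
    """Outlier calling repeated per focus sample and per cohort design.

    ``cohort_names`` may mix predefined cohorts (pan_cancer, tcga_only,
    pediatric, institution) and personalized ones (similarity computed once
    on the filtered gene space unless supplied).  Detection sets are
    (focus, gene) pairs over the shared ``gene_space`` (default: all genes).
    """
    params = params or Parameters()
    genes = list(gene_space) if gene_space is not None else c.genes
    need_personalized = any(n in PAN_DISEASE_COHORTS for n in cohort_names)
    if need_personalized and sim is None:
        space = pan_cancer_gene_space(c, params).retained
        sim = compute_similarity(c, params, space or None)

    per_cohort: Dict[str, Set[Pair]] = {name: set() for name in cohort_names}
    diagnostics: Dict[Tuple[str, str], Dict[str, float]] = {}
    unusable: Dict[str, List[str]] = {}
    for focus in focus_set:
        cohorts: Dict[str, CohortSpec] = {}
        predefined = build_predefined_cohorts(focus, c, params)
        cohorts.update({n: s for n, s in predefined.items() if n in cohort_names})
        if need_personalized:
            personalized = build_pan_disease_cohorts(focus, c, sim, params)
            cohorts.update({n: s for n, s in personalized.items() if n in cohort_names})
        missing = [n for n in cohort_names if n not in cohorts]
        if missing:
            raise ValueError(f"unknown cohort name(s): {missing}")
        profile = c.focus_profile(focus)
        for name in cohort_names:
            spec = cohorts[name]
            if not spec.usable(params.min_cohort_size):
                unusable.setdefault(focus, []).append(name)
                continue
            calls = call_outliers(profile, spec, c, genes, params)
            for g in outlier_gene_set(calls):
                per_cohort[name].add((focus, g))

        # diagnostics for every gene any cohort detected for this focus
        detected_genes = {g for name in cohort_names for (f, g) in per_cohort[name] if f == focus}
        for g in detected_genes:
            for name, stats_d in distribution_diagnostics(g, cohorts, c, params).items():
                diagnostics[(g, name)] = stats_d

    return ComparisonResult(
        per_cohort_outliers=per_cohort,
        intersections=exclusive_intersections(per_cohort),
        diagnostics=diagnostics,
        unusable_cohorts=unusable,
    )


def added_findings(
    personalized: Mapping[str, Set[str]],
    predefined: Mapping[str, Set[str]],
) -> Dict[str, Optional[float]]:
    """How many findings the personalized analysis adds over predefined cohorts.

    Inputs map focus sample -> detected gene set; accounting is per
    (focus, gene) pair.  ``pct_added`` is reported in percent of the
    predefined count, or None (with a warning) when no predefined findings
    exist.
    """
    personal_pairs = {(f, g) for f, genes in personalized.items() for g in genes}
    predefined_pairs = {(f, g) for f, genes in predefined.items() for g in genes}
    added = personal_pairs - predefined_pairs
    n_predef = len(predefined_pairs)
    pct: Optional[float]
    if n_predef == 0:
        if added:
            logger.warning(
                "no predefined findings but %d personalized ones; pct_added undefined",
                len(added),
            )
        pct = None
    else:
        pct = 100.0 * len(added) / n_predef
    return {
        "n_predefined": n_predef,
        "n_union": len(predefined_pairs | personal_pairs),
        "n_added": len(added),
        "pct_added": pct,
    }


# -- compendium-version comparison ------------------------------------------


def pan_disease_analysis(
    focus: str,
    c: ExpressionCompendium,
    params: Parameters,
    gene_space: Optional[Sequence[str]] = None,
    sim: Optional[SimilarityResult] = None,
) -> Dict:
    """One focus sample's personalized pan-disease analysis on one compendium.

    Similarity is computed on the pan-cancer filtered gene space (recomputed
    per compendium unless a threshold override pins it); outlier calling
    uses the unfiltered gene list unless ``gene_space`` narrows it.
    """
    if sim is None:
        space = pan_cancer_gene_space(c, params).retained
        sim = compute_similarity(c, params, space or None)
    cohorts = build_pan_disease_cohorts(focus, c, sim, params)
    profile = c.focus_profile(focus)
    genes = list(gene_space) if gene_space is not None else c.genes
    per_cohort_calls = {
        name: call_outliers(profile, spec, c, genes, params) for name, spec in cohorts.items()
    }
    consensus, single = consensus_pan_disease(per_cohort_calls, params.consensus_min_cohorts)
    top_samples = top_k_correlated(sim.correlations, focus, params.top_k_correlated)
    top6_diseases = {normalize_disease(c.metadata[s].disease) for s in top_samples}
    return {
        "sim": sim,
        "cohorts": cohorts,
        "per_cohort_calls": per_cohort_calls,
        "consensus": consensus,
        "single_cohort": single,
        "top6_diseases": top6_diseases,
    }


def compendium_version_diff(
    focus: str,
    c_old: ExpressionCompendium,
    c_new: ExpressionCompendium,
    params: Optional[Parameters] = None,
    gene_space: Optional[Sequence[str]] = None,
) -> Dict:
    """Re-run the personalized analysis on two compendium versions.

    Classifies every gene that is a consensus or single-cohort outlier in
    either version as gained / lost / unchanged consensus status, and
    records the responsible cohort-composition change (top-6 disease set
    difference and per-cohort size changes).
    """
    params = params or Parameters()
    if list(c_old.genes) != list(c_new.genes):
        raise ValueError("compendium versions must share the same gene space")
    old = pan_disease_analysis(focus, c_old, params, gene_space)
    new = pan_disease_analysis(focus, c_new, params, gene_space)

    def tier(res: Dict, g: str) -> str:
        if g in res["consensus"]:
            return "consensus"
        if g in res["single_cohort"]:
            return "single_cohort"
        return "none"

    interesting = old["consensus"] | old["single_cohort"] | new["consensus"] | new["single_cohort"]
    transitions: Dict[str, Dict[str, str]] = {}
    for g in sorted(interesting):
        t_old, t_new = tier(old, g), tier(new, g)
        if (g in old["consensus"]) and (g not in new["consensus"]):
            status = "lost"
        elif (g not in old["consensus"]) and (g in new["consensus"]):
            status = "gained"
        else:
            status = "unchanged"
        calling_old = sorted(
            name
            for name, calls in old["per_cohort_calls"].items()
            if g in outlier_gene_set(calls)
        )
        calling_new = sorted(
            name
            for name, calls in new["per_cohort_calls"].items()
            if g in outlier_gene_set(calls)
        )
        transitions[g] = {
            "status": status,
            "tier_old": t_old,
            "tier_new": t_new,
            "cohorts_old": ",".join(calling_old),
            "cohorts_new": ",".join(calling_new),
        }

    changed_cohorts = sorted(
        name
        for name in PAN_DISEASE_COHORTS
        if old["cohorts"][name].members != new["cohorts"][name].members
    )
    return {
        "transitions": transitions,
        "top6_diseases_old": sorted(old["top6_diseases"]),
        "top6_diseases_new": sorted(new["top6_diseases"]),
        "changed_cohorts": changed_cohorts,
        "cohort_sizes_old": {n: old["cohorts"][n].size for n in PAN_DISEASE_COHORTS},
        "cohort_sizes_new": {n: new["cohorts"][n].size for n in PAN_DISEASE_COHORTS},
        "similarity_threshold_old": old["sim"].threshold,
        "similarity_threshold_new": new["sim"].threshold,
    }
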