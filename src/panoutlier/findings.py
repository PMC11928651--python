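"""Findings: classification, druggability, pathway support, report assembly.

An outlier gene becomes a *finding* with

* a finding type partitioning all findings: ``both`` (pan-cancer and
  consensus pan-disease), ``pan_cancer_only``, ``pan_disease_only``, or
  ``curated`` (identified only through human-curation tiers: a curated
  substitute cohort, a single pan-disease cohort, mutation-implicated, or
  the highly-expressed review list);
* a druggability flag from a static druggable-gene list (automated reports
  only include druggable findings; the rest stay visible to curation);
* pathway support: membership in at least one gene set whose overlap with
  the overexpressed-gene query is significant (upper-tail hypergeometric
  test, Benjamini–Hochberg adjusted) at the configured cutoff.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .compendium import GeneSetCollection
from .outliers import OutlierCall
from .params import Parameters

logger = logging.getLogger(__name__)

FINDING_TYPES = ("pan_cancer_only", "pan_disease_only", "both", "curated")
CURATION_SUBTYPES = ("curated_cohort", "single_cohort", "highly_expressed", "mutation_implicated")


@dataclass
class Finding:
    gene: str
    focus: str
    finding_type: str
    curation_subtype: Optional[str] = None
    druggable: bool = False
    pathway_support: bool = False
    evidence: List[OutlierCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.finding_type not in FINDING_TYPES:
            raise ValueError(f"unknown finding_type {self.finding_type!r}")
        if self.curation_subtype is not None and self.curation_subtype not in CURATION_SUBTYPES:
            raise ValueError(f"unknown curation_subtype {self.curation_subtype!r}")
        if (self.finding_type == "curated") != (self.curation_subtype is not None):
            raise ValueError("curation_subtype set iff finding_type == 'curated'")


@dataclass
class CurationInputs:
    """Genes surfaced by the human-curation tiers (may overlap automated)."""

    curated_consensus: Set[str] = field(default_factory=set)
    single_cohort: Set[str] = field(default_factory=set)
    highly_expressed: Set[str] = field(default_factory=set)
    mutation_implicated: Set[str] = field(default_factory=set)


def classify_findings(
    focus: str,
    pan_cancer_outliers: Set[str],
    consensus_outliers: Set[str],
    curation: Optional[CurationInputs] = None,
    evidence: Optional[Mapping[str, Sequence[OutlierCall]]] = None,
) -> List[Finding]:
    """Assign exactly one finding type per distinct gene.

    Automated findings come first (``both`` / ``pan_cancer_only`` /
    ``pan_disease_only``); curation tiers only contribute genes not already
    automated, in priority order curated-cohort consensus > single cohort >
    mutation-implicated > highly expressed.
    """
    curation = curation or CurationInputs()
    evidence = evidence or {}
    findings: List[Finding] = []
    seen: Set[str] = set()

    def _add(gene: str, ftype: str, subtype: Optional[str] = None) -> None:
        findings.append(
            Finding(
                gene=gene,
                focus=focus,
                finding_type=ftype,
                curation_subtype=subtype,
                evidence=list(evidence.get(gene, [])),
            )
        )
        seen.add(gene)

    for g in sorted(pan_cancer_outliers & consensus_outliers):
        _add(g, "both")
    for g in sorted(pan_cancer_outliers - consensus_outliers):
        _add(g, "pan_cancer_only")
    for g in sorted(consensus_outliers - pan_cancer_outliers):
        _add(g, "pan_disease_only")
    for subtype, genes in (
        ("curated_cohort", curation.curated_consensus),
        ("single_cohort", curation.single_cohort),
        ("mutation_implicated", curation.mutation_implicated),
        ("highly_expressed", curation.highly_expressed),
    ):
        for g in sorted(genes - seen):
            _add(g, "curated", subtype)
    return findings


def druggable_filter(findings: List[Finding], druggable: Iterable[str]) -> List[Finding]:
    """Annotate findings with druggability (case-normalized match).

    Returns the same findings with the ``druggable`` flag set; callers
    decide whether to restrict reports to druggable findings.  An empty
    list yields all-false with a warning.
    """
    druggable = list(druggable)
    if not druggable:
        logger.warning("druggable gene list is empty; every finding marked non-druggable")
    exact = set(druggable)
    folded = {g.casefold(): g for g in druggable}
    for f in findings:
        if f.gene in exact:
            f.druggable = True
        elif f.gene.casefold() in folded:
            logger.warning(
                "gene %r matched druggable list entry %r only after case folding",
                f.gene,
                folded[f.gene.casefold()],
            )
            f.druggable = True
        else:
            f.druggable = False
    return findings


# -- gene-set overlap --------------------------------------------------------


@dataclass(frozen=True)
class OverlapTestResult:
    set_name: str
    universe_size: int
    set_size: int
    query_size: int
    overlap: int
    p_value: float
    p_adjusted: float


def hypergeometric_overlap_p(
    universe_size: int, set_size: int, query_size: int, overlap: int
) -> float:
    """Upper-tail P(X >= overlap) for draws of ``query_size`` from a universe
    containing ``set_size`` marked genes."""
    if overlap > min(set_size, query_size):
        raise ValueError("overlap cannot exceed min(set_size, query_size)")
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def pathway_overlap_test(
    query: Set[str],
    collection: GeneSetCollection,
    universe: Set[str],
) -> List[OverlapTestResult]:
    """Hypergeometric overlap of the query gene list with every gene set.

    Sets are intersected with the universe before testing; results are
    sorted by raw p ascending (ties by set name) and carry BH-adjusted
    values.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    stray = query - universe
    if stray:
        raise ValueError(f"query gene(s) outside the universe: {sorted(stray)[:5]}")
    m = len(universe)
    n_query = len(query)
    rows = []
    for name in sorted(collection.sets):
        members = set(collection.sets[name]) & universe
        k = len(members & query)
        p = hypergeometric_overlap_p(m, len(members), n_query, k)
        rows.append((name, len(members), k, p))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    results = [
        OverlapTestResult(
            set_name=name,
            universe_size=m,
            set_size=set_size,
            query_size=n_query,
            overlap=k,
            p_value=p,
            p_adjusted=float(p_adj),
        )
        for (name, set_size, k, p), p_adj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def annotate_pathway_support(
    findings: List[Finding],
    overlap_results: Sequence[OverlapTestResult],
    collection: GeneSetCollection,
    fdr_cutoff: float,
) -> List[Finding]:
    """pathway_support = membership in >=1 significant set (BH p < cutoff)."""
    significant = {r.set_name for r in overlap_results if r.p_adjusted < fdr_cutoff}
    supported_genes: Set[str] = set()
    for name in significant:
        supported_genes |= set(collection.sets.get(name, frozenset()))
    for f in findings:
        f.pathway_support = f.gene in supported_genes
    return findings


# -- report assembly ---------------------------------------------------------

REPORT_SCHEMA_VERSION = "1.0"


def assemble_report(
    focus: str,
    findings: Sequence[Finding],
    overlap_results: Sequence[OverlapTestResult],
    params: Parameters,
    cohort_summaries: Optional[Sequence[Mapping]] = None,
    similarity_summary: Optional[Mapping] = None,
    qc_status: str = "pass",
) -> dict:
    """Deterministic JSON-ready report document."""
    finding_rows = []
    for f in sorted(findings, key=lambda f: (FINDING_TYPES.index(f.finding_type), f.gene)):
        finding_rows.append(
            {
                "gene": f.gene,
                "finding_type": f.finding_type,
                "curation_subtype": f.curation_subtype,
                "druggable": f.druggable,
                "pathway_support": f.pathway_support,
                "evidence": [
                    {
                        "cohort": e.cohort,
                        "q75": e.q75,
                        "iqr": e.iqr,
                        "threshold": e.threshold,
                        "focus_expression": e.focus_expression,
                        "is_outlier": e.is_outlier,
                    }
                    for e in sorted(f.evidence, key=lambda e: e.cohort)
                ],
            }
        )
    counts = {t: 0 for t in FINDING_TYPES}
    for f in findings:
        counts[f.finding_type] += 1
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "focus": focus,
        "qc_status": qc_status,
        "parameters": params.to_dict(),
        "similarity": dict(similarity_summary) if similarity_summary else None,
        "cohorts": [dict(s) for s in cohort_summaries] if cohort_summaries else [],
        "finding_type_counts": counts,
        "n_findings": len(finding_rows),
        "findings": finding_rows,
        "pathway_overlap": [
            {
                "set_name": r.set_name,
                "universe_size": r.universe_size,
                "set_size": r.set_size,
                "query_size": r.query_size,
                "overlap": r.overlap,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
            }
            for r in overlap_results
        ],
    }


def write_report(report: dict, out_dir: str | Path) -> Dict[str, Path]:
    """Write the report as canonical JSON plus a flat findings TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / f"report_{report['focus']}.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    rows = []
    for f in report["findings"]:
        evidence_cohorts = ";".join(e["cohort"] for e in f["evidence"] if e["is_outlier"])
        rows.append(
            {
                "focus": report["focus"],
                "gene": f["gene"],
                "finding_type": f["finding_type"],
                "curation_subtype": f["curation_subtype"] or "",
                "druggable": f["druggable"],
                "pathway_support": f["pathway_support"],
                "outlier_cohorts": evidence_cohorts,
            }
        )
    tsv_path = out_dir / f"findings_{report['focus']}.tsv"
    columns = [
        "focus",
        "gene",
        "finding_type",
        "curation_subtype",
        "druggable",
        "pathway_support",
        "outlier_cohorts",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(tsv_path, sep="\t", index=False)
    return {"json": json_path, "tsv": tsv_path}
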