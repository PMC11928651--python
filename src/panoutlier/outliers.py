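"""Tukey outlier calling, consensus logic, and curation-tier helpers.

A gene is an expression outlier in the focus sample, relative to a
comparator cohort, when its expression strictly exceeds the Tukey upper
fence of the cohort distribution:

    threshold = Q75 + 1.5 * IQR

with quartiles computed by linear interpolation between order statistics.
A gene called in at least two of the four personalized pan-disease cohorts
is a *consensus* pan-disease outlier; one called in exactly one cohort is
routed to the human-curation tier instead of the automated findings.

Two further curation-tier helpers: the within-sample 95th-percentile
highly-expressed review list, and the fallback rule for QC-failed profiles
(restrict candidates to genes above 8.5 log2(TPM+1), which coincides with
such a profile's own 95th percentile).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .cohorts import CohortSpec
from .compendium import ExpressionCompendium, FocusProfile
from .params import Parameters

logger = logging.getLogger(__name__)


def tukey_threshold(
    values: Sequence[float],
    iqr_multiplier: float = 1.5,
    quartile_upper: float = 0.75,
) -> Tuple[float, float, float]:
    """(q75, iqr, threshold) for one gene's cohort expression vector."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need >= 2 values for quartiles, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ValueError("expression values must be finite")
    q25, q75 = np.quantile(arr, [1.0 - quartile_upper, quartile_upper]).tolist()
    iqr = q75 - q25
    return q75, iqr, q75 + iqr_multiplier * iqr


@dataclass(frozen=True)
class OutlierCall:
    """One gene's threshold and call against one comparator cohort."""

    gene: str
    cohort: str
    q75: float
    iqr: float
    threshold: float
    focus_expression: float
    is_outlier: bool

    @property
    def margin(self) -> float:
        return self.focus_expression - self.threshold


def call_outliers(
    focus_profile: FocusProfile | pd.Series,
    cohort: CohortSpec,
    c: ExpressionCompendium,
    gene_space: Optional[Sequence[str]] = None,
    params: Optional[Parameters] = None,
) -> List[OutlierCall]:
    """Tukey calls for every gene in ``gene_space`` against one cohort.

    Unusable (undersized) cohorts contribute no calls: an empty list is
    returned with a warning.  Calls are sorted by exceedance margin
    (focus expression minus threshold) descending, ties by gene id.
    """
    params = params or Parameters()
    expr = focus_profile.expression if isinstance(focus_profile, FocusProfile) else focus_profile
    focus_id = (
        focus_profile.sample_id if isinstance(focus_profile, FocusProfile) else str(expr.name)
    )
    if not cohort.usable(params.min_cohort_size):
        logger.warning(
            "cohort %s (%d members) below min size %d; no outlier calls made",
            cohort.name,
            cohort.size,
            params.min_cohort_size,
        )
        return []
    if focus_id in cohort.members:
        raise ValueError(f"focus sample {focus_id!r} must not be a member of its cohort")
    genes = list(gene_space) if gene_space is not None else c.genes
    members = sorted(cohort.members)
    matrix = c.values.loc[genes, members].to_numpy()
    q75 = np.quantile(matrix, params.quartile_upper, axis=1)
    q25 = np.quantile(matrix, 1.0 - params.quartile_upper, axis=1)
    iqr = q75 - q25
    thresholds = q75 + params.iqr_multiplier * iqr
    focus_values = expr.loc[genes].to_numpy(dtype=float)
    calls = [
        OutlierCall(
            gene=g,
            cohort=cohort.name,
            q75=float(q),
            iqr=float(i),
            threshold=float(t),
            focus_expression=float(f),
            is_outlier=bool(f > t),
        )
        for g, q, i, t, f in zip(genes, q75, iqr, thresholds, focus_values)
    ]
    calls.sort(key=lambda call: (-(call.margin), call.gene))
    return calls


def outlier_gene_set(calls: Sequence[OutlierCall]) -> Set[str]:
    return {call.gene for call in calls if call.is_outlier}


def consensus_pan_disease(
    per_cohort_calls: Mapping[str, Sequence[OutlierCall]],
    min_cohorts: int = 2,
) -> Tuple[Set[str], Set[str]]:
    """Split pan-disease outliers into consensus and single-cohort tiers.

    Consensus: outlier in >= ``min_cohorts`` of the (usable) personalized
    cohorts — an automated finding.  Single-cohort: outlier in exactly one —
    routed to human curation, never reported as automated.
    """
    counts: Dict[str, int] = {}
    for calls in per_cohort_calls.values():
        for g in outlier_gene_set(calls):
            counts[g] = counts.get(g, 0) + 1
    consensus = {g for g, n in counts.items() if n >= min_cohorts}
    single = {g for g, n in counts.items() if n == 1}
    return consensus, single


def highly_expressed_genes(
    focus_profile: FocusProfile | pd.Series, percentile: float
) -> Set[str]:
    """Genes strictly above the focus profile's own expression percentile.

    The curation review tier: highly expressed genes that may not have
    reached any cohort threshold.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError(f"percentile must be in (0, 1), got {percentile}")
    expr = focus_profile.expression if isinstance(focus_profile, FocusProfile) else focus_profile
    cutoff = float(np.quantile(expr.to_numpy(dtype=float), percentile))
    return set(expr.index[expr > cutoff])


def qc_fail_filter(
    focus_profile: FocusProfile,
    cutoff: Optional[float] = None,
    params: Optional[Parameters] = None,
) -> Tuple[Set[str], float]:
    """Candidate genes for a QC-failed profile, plus the profile's own 95th
    percentile.

    QC-failed datasets (e.g. dominated by duplicate reads) get a hard
    expression floor: only genes strictly above ``cutoff`` log2(TPM+1)
    (default 8.5) remain candidates.  The profile's 95th percentile is
    reported alongside because the default cutoff is calibrated to coincide
    with it.
    """
    params = params or Parameters()
    if focus_profile.qc_status != "fail":
        raise ValueError(
            f"qc_fail_filter applies only to QC-failed profiles; "
            f"{focus_profile.sample_id!r} has qc_status="
            f"{focus_profile.qc_status!r}"
        )
    cutoff = params.qc_fail_expression_cutoff if cutoff is None else cutoff
    expr = focus_profile.expression
    p95 = float(np.quantile(expr.to_numpy(dtype=float), 0.95))
    return set(expr.index[expr > cutoff]), p95
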