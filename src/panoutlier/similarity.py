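"""Pairwise Spearman similarity, compendium-wide threshold, neighbor search.

Two tumors are "molecularly similar" when the Spearman correlation of their
expression profiles is strictly above a compendium-wide threshold: by
default the 95th percentile of all pairwise correlations (each unordered
pair counted once, self-pairs excluded), or a fixed override (e.g. 0.875)
pinned to a particular compendium version.

Quantiles everywhere in this package use linear interpolation between order
statistics (position 1 + q*(n-1)), numpy's default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .compendium import ExpressionCompendium
from .params import Parameters

logger = logging.getLogger(__name__)


def spearman(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Spearman rank correlation with average ranks for ties.

    Returns None (with a warning) when either vector has zero variance,
    where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need vectors of length >= 3, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("spearman undefined for a zero-variance vector; returning None")
        return None
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def pairwise_spearman(
    c: ExpressionCompendium, gene_space: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """All-pairs Spearman correlation between sample profiles.

    Returns a symmetric samples x samples DataFrame with unit diagonal.
    """
    values = c.values if gene_space is None else c.values.loc[list(gene_space)]
    if values.shape[0] < 3:
        raise ValueError("need >= 3 genes to correlate sample profiles")
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    # rank genes within each sample, then Pearson on ranks == Spearman
    ranks = values.rank(axis=0, method="average").to_numpy()
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr = np.atleast_2d(corr)
    return pd.DataFrame(corr, index=c.samples, columns=c.samples)


@dataclass
class SimilarityResult:
    correlations: pd.DataFrame
    threshold: float
    method: str  # "percentile" or "override"

    def rho(self, a: str, b: str) -> float:
        return float(self.correlations.at[a, b])


def similarity_threshold(
    correlations: pd.DataFrame,
    percentile: float,
    override: Optional[float] = None,
) -> Tuple[float, str]:
    """Similarity cutoff: the given percentile of all unordered off-diagonal
    pair correlations, or a fixed override when one is pinned."""
    if override is not None:
        return float(override), "override"
    n = correlations.shape[0]
    if n < 2:
        raise ValueError("need >= 2 samples to form at least one pair")
    iu = np.triu_indices(n, k=1)
    pair_values = correlations.to_numpy()[iu]
    if pair_values.size < 2:
        raise ValueError("need >= 2 distinct pairs for a percentile threshold")
    return float(np.quantile(pair_values, percentile)), "percentile"


def compute_similarity(
    c: ExpressionCompendium,
    params: Parameters,
    gene_space: Optional[Sequence[str]] = None,
) -> SimilarityResult:
    corr = pairwise_spearman(c, gene_space)
    thr, method = similarity_threshold(
        corr, params.similarity_percentile, params.similarity_threshold_override
    )
    return SimilarityResult(correlations=corr, threshold=thr, method=method)


def first_degree_neighbors(
    correlations: pd.DataFrame, focus: str, threshold: float
) -> Set[str]:
    """Samples whose correlation with the focus is strictly above threshold."""
    rhos = correlations[focus].drop(index=focus)
    return set(rhos.index[rhos > threshold])


def second_degree_neighbors(
    correlations: pd.DataFrame, focus: str, threshold: float
) -> Set[str]:
    """First-degree neighbors plus the samples similar to them (focus excluded)."""
    first = first_degree_neighbors(correlations, focus, threshold)
    out = set(first)
    for n in first:
        rhos = correlations[n].drop(index=n)
        out |= set(rhos.index[rhos > threshold])
    out.discard(focus)
    return out


def top_k_correlated(correlations: pd.DataFrame, focus: str, k: int) -> List[str]:
    """The k samples most correlated with the focus, rho descending.

    Ties are broken by lexicographic sample id.  If fewer than k other
    samples exist, all are returned with a warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    rhos = correlations[focus].drop(index=focus)
    ranked = sorted(rhos.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < k:
        logger.warning(
            "only %d samples available for top-%d correlated list", len(ranked), k
        )
    return [s for s, _ in ranked[:k]]
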