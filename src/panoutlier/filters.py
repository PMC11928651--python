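"""Gene-space filters for the pan-cancer analysis.

Pan-cancer outlier calling (and, by default, molecular-similarity
computation) runs on an expression- and variance-filtered gene space.  Two
stages, in fixed order:

1. zero-expression filter: drop any gene for which >= 80% of samples have
   an expression of exactly 0;
2. variance filter: of the survivors, drop the 20% with the lowest sample
   variance, regardless of absolute variance (ties broken by gene id for
   determinism).

The pan-disease analysis intentionally uses the unfiltered gene list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .compendium import ExpressionCompendium
from .params import Parameters

logger = logging.getLogger(__name__)


@dataclass
class FilteredGeneSpace:
    """Disjoint partition of the input genes into retained / dropped sets."""

    retained: List[str]
    dropped_zero: frozenset
    dropped_variance: frozenset

    def __post_init__(self) -> None:
        self.dropped_zero = frozenset(self.dropped_zero)
        self.dropped_variance = frozenset(self.dropped_variance)
        overlap = (
            (set(self.retained) & self.dropped_zero)
            | (set(self.retained) & self.dropped_variance)
            | (self.dropped_zero & self.dropped_variance)
        )
        if overlap:
            raise ValueError(f"retained/dropped sets overlap: {sorted(overlap)[:5]}")


def expression_zero_filter(
    c: ExpressionCompendium, cutoff: float
) -> Tuple[List[str], List[str]]:
    """Drop genes whose fraction of exactly-zero samples is >= ``cutoff``."""
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    if c.n_genes == 0 or c.n_samples == 0:
        raise ValueError("cannot filter an empty compendium")
    zero_frac = (c.values.to_numpy() == 0.0).mean(axis=1)
    dropped_mask = zero_frac >= cutoff
    kept = [g for g, d in zip(c.genes, dropped_mask) if not d]
    dropped = [g for g, d in zip(c.genes, dropped_mask) if d]
    return kept, dropped


def variance_filter(
    c: ExpressionCompendium, genes: List[str], drop_fraction: float
) -> Tuple[List[str], List[str]]:
    """Drop the ``drop_fraction`` of ``genes`` with the lowest sample variance.

    Variance is the unbiased (n-1) sample variance.  Exactly
    floor(drop_fraction * len(genes)) genes are dropped; ties are broken by
    lexicographic gene id so results do not depend on input order.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError(f"drop_fraction must be in [0, 1), got {drop_fraction}")
    n_drop = math.floor(drop_fraction * len(genes))
    if n_drop == 0:
        return list(genes), []
    variances = c.values.loc[genes].var(axis=1, ddof=1)
    order = sorted(genes, key=lambda g: (variances[g], g))
    dropped = set(order[:n_drop])
    kept = [g for g in genes if g not in dropped]
    return kept, order[:n_drop]


def pan_cancer_gene_space(c: ExpressionCompendium, params: Parameters) -> FilteredGeneSpace:
    """Apply the zero-expression filter, then the variance filter."""
    kept, dropped_zero = expression_zero_filter(c, params.zero_fraction_cutoff)
    if not kept:
        logger.warning("every gene failed the zero-expression filter; retained set is empty")
        return FilteredGeneSpace(retained=[], dropped_zero=dropped_zero, dropped_variance=[])
    retained, dropped_var = variance_filter(c, kept, params.variance_drop_fraction)
    return FilteredGeneSpace(
        retained=retained, dropped_zero=dropped_zero, dropped_variance=dropped_var
    )
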