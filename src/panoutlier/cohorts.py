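"""Comparator-cohort construction.

Two families of comparator cohorts are built for a focus sample:

* four *personalized* pan-disease cohorts — (1) samples with the same
  diagnosis, (2) first-degree molecular neighbors, (3) first plus second
  degree neighbors, (4) all samples of the diseases seen among the top-6
  most correlated datasets;
* four *predefined* cohorts — the full compendium (pan-cancer), all TCGA
  datasets, pediatric patients (age at diagnosis < 30 years), and the
  single-institution cohort.

A curated cohort of clinically similar diseases can replace an empty or
undersized same-disease cohort; findings derived from it stay flagged as
curation-derived end to end.  The focus sample is excluded from every
cohort so thresholds describe the background, never the focus itself.
Cohorts below the configured minimum size are flagged unusable rather than
silently dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set

from .compendium import ExpressionCompendium
from .params import Parameters
from .similarity import (
    SimilarityResult,
    first_degree_neighbors,
    second_degree_neighbors,
    top_k_correlated,
)

logger = logging.getLogger(__name__)

PAN_DISEASE_COHORTS = ("same_disease", "first_degree", "first_second_degree", "top6_diseases")
PREDEFINED_COHORTS = ("pan_cancer", "tcga_only", "pediatric", "institution")
COHORT_NAMES = PAN_DISEASE_COHORTS + PREDEFINED_COHORTS + ("curated",)


def normalize_disease(label: str) -> str:
    """Case/whitespace-normalized disease label for exact matching."""
    return re.sub(r"\s+", " ", label.strip()).casefold()


@dataclass(frozen=True)
class CohortSpec:
    """A named comparator cohort with the rule that produced it."""

    name: str
    members: frozenset
    provenance: str
    curated_flag: bool = False

    def __post_init__(self) -> None:
        if self.name not in COHORT_NAMES:
            raise ValueError(f"cohort name must be one of {COHORT_NAMES}, got {self.name!r}")
        if self.curated_flag != (self.name == "curated"):
            raise ValueError("curated_flag must be True exactly for the 'curated' cohort")
        object.__setattr__(self, "members", frozenset(self.members))

    @property
    def size(self) -> int:
        return len(self.members)

    def usable(self, min_size: int) -> bool:
        return self.size >= min_size


def build_pan_disease_cohorts(
    focus: str,
    c: ExpressionCompendium,
    sim: SimilarityResult,
    params: Parameters,
) -> Dict[str, CohortSpec]:
    """The four personalized cohorts for one focus sample."""
    if c.metadata is None:
        raise ValueError("metadata (disease labels) required for pan-disease cohorts")
    if focus not in set(c.samples):
        raise KeyError(f"unknown focus sample {focus!r}")
    focus_disease = normalize_disease(c.metadata[focus].disease)
    if not focus_disease:
        raise ValueError(f"focus sample {focus!r} has no disease label")

    same = {
        s
        for s in c.samples
        if s != focus and normalize_disease(c.metadata[s].disease) == focus_disease
    }
    first = first_degree_neighbors(sim.correlations, focus, sim.threshold)
    second = second_degree_neighbors(sim.correlations, focus, sim.threshold)
    top_k = top_k_correlated(sim.correlations, focus, params.top_k_correlated)
    top_diseases = {normalize_disease(c.metadata[s].disease) for s in top_k}
    top6 = {
        s
        for s in c.samples
        if s != focus and normalize_disease(c.metadata[s].disease) in top_diseases
    }

    cohorts = {
        "same_disease": CohortSpec(
            "same_disease",
            frozenset(same),
            f"disease label == {focus_disease!r}",
        ),
        "first_degree": CohortSpec(
            "first_degree",
            frozenset(first - {focus}),
            f"spearman rho > {sim.threshold:.4f} ({sim.method})",
        ),
        "first_second_degree": CohortSpec(
            "first_second_degree",
            frozenset(second - {focus}),
            f"two-hop closure at rho > {sim.threshold:.4f} ({sim.method})",
        ),
        "top6_diseases": CohortSpec(
            "top6_diseases",
            frozenset(top6),
            f"diseases of top-{params.top_k_correlated} correlated: "
            + ", ".join(sorted(top_diseases)),
        ),
    }
    for spec in cohorts.values():
        if not spec.usable(params.min_cohort_size):
            logger.warning(
                "cohort %s for focus %s has %d members (< %d); flagged unusable",
                spec.name,
                focus,
                spec.size,
                params.min_cohort_size,
            )
    return cohorts


def build_predefined_cohorts(
    focus: str,
    c: ExpressionCompendium,
    params: Parameters,
) -> Dict[str, CohortSpec]:
    """The four predefined cohorts: full compendium, TCGA, pediatric, institution.

    Samples with a missing age at diagnosis are excluded from the pediatric
    cohort with a warning (conservative: an age-filtered cohort only admits
    samples whose age is known).
    """
    if c.metadata is None:
        raise ValueError("metadata (source, age) required for predefined cohorts")
    others = [s for s in c.samples if s != focus]
    missing_age = [s for s in others if c.metadata[s].age_at_diagnosis is None]
    if missing_age:
        logger.warning(
            "%d sample(s) have no age at diagnosis and are excluded from the "
            "pediatric cohort (first few: %s)",
            len(missing_age),
            missing_age[:5],
        )
    pediatric = {
        s
        for s in others
        if c.metadata[s].age_at_diagnosis is not None
        and c.metadata[s].age_at_diagnosis < params.pediatric_age_cutoff
    }
    return {
        "pan_cancer": CohortSpec("pan_cancer", frozenset(others), "full compendium"),
        "tcga_only": CohortSpec(
            "tcga_only",
            frozenset(s for s in others if c.metadata[s].source == "tcga"),
            "source == tcga",
        ),
        "pediatric": CohortSpec(
            "pediatric",
            frozenset(pediatric),
            f"age at diagnosis < {params.pediatric_age_cutoff:g} years",
        ),
        "institution": CohortSpec(
            "institution",
            frozenset(s for s in others if c.metadata[s].source == "institution"),
            "source == institution",
        ),
    }


def substitute_curated_cohort(
    focus: str,
    c: ExpressionCompendium,
    curated_diseases: Iterable[str],
) -> CohortSpec:
    """Curated replacement for an empty/undersized same-disease cohort.

    Members are all samples whose disease is in the curated set (e.g. several
    clinically similar soft-tissue sarcoma types combined).  Downstream
    findings that rely on this cohort are tagged curation-derived.
    """
    if c.metadata is None:
        raise ValueError("metadata required for curated cohort")
    curated = {normalize_disease(d) for d in curated_diseases if d.strip()}
    if not curated:
        raise ValueError("curated disease set is empty")
    members = {
        s
        for s in c.samples
        if s != focus and normalize_disease(c.metadata[s].disease) in curated
    }
    if not members:
        raise ValueError(f"curated diseases {sorted(curated)} match no compendium samples")
    return CohortSpec(
        "curated",
        frozenset(members),
        "curated diseases: " + ", ".join(sorted(curated)),
        curated_flag=True,
    )
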