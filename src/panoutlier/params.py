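"""Tunable parameters of the comparative outlier pipeline.

Every numeric constant the pipeline uses lives here, so that a single YAML
file documents a run completely.  Defaults are the values of the production
protocol: Tukey multiplier 1.5 on the interquartile range above the 75th
percentile, molecular similarity at the 95th percentile of all pairwise
Spearman correlations (optionally overridden with a fixed rho such as 0.875),
top-6 most-correlated neighbors, consensus at >=2 of the four personalized
cohorts, the 80% zero-expression and 20% low-variance gene filters, the
<30-years pediatric age cutoff, the 95th-percentile highly-expressed review
tier, and the 8.5 log2(TPM+1) fallback cutoff for QC-failed profiles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import yaml


@dataclass
class Parameters:
    iqr_multiplier: float = 1.5
    quartile_upper: float = 0.75
    similarity_percentile: float = 0.95
    similarity_threshold_override: Optional[float] = None
    top_k_correlated: int = 6
    consensus_min_cohorts: int = 2
    zero_fraction_cutoff: float = 0.80
    variance_drop_fraction: float = 0.20
    pediatric_age_cutoff: float = 30.0
    highly_expressed_percentile: float = 0.95
    qc_fail_expression_cutoff: float = 8.5
    min_cohort_size: int = 20
    pathway_fdr_cutoff: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "quartile_upper",
            "similarity_percentile",
            "zero_fraction_cutoff",
            "highly_expressed_percentile",
            "pathway_fdr_cutoff",
        ):
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v!r}")
        if not 0.0 <= self.variance_drop_fraction < 1.0:
            raise ValueError(
                f"variance_drop_fraction must be in [0, 1), got {self.variance_drop_fraction!r}"
            )
        if self.iqr_multiplier < 0:
            raise ValueError("iqr_multiplier must be >= 0")
        if self.similarity_threshold_override is not None and not (
            -1.0 <= self.similarity_threshold_override <= 1.0
        ):
            raise ValueError("similarity_threshold_override must be a correlation in [-1, 1]")
        if self.top_k_correlated < 1:
            raise ValueError("top_k_correlated must be >= 1")
        if self.consensus_min_cohorts < 1:
            raise ValueError("consensus_min_cohorts must be >= 1")
        if self.min_cohort_size < 2:
            raise ValueError("min_cohort_size must be >= 2 (a quartile needs two values)")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Parameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Parameters":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ValueError(f"parameter file {path} must contain a mapping")
        return cls.from_dict(data)
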