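"""Synthetic expression compendia with known ground truth.

The generator emulates the structure of a multi-disease tumor RNA-seq
compendium on the log2(TPM+1) scale: each disease has a characteristic mean
profile, samples are that profile plus i.i.d. Gaussian noise clipped at
zero, ages are drawn so that a requested share of patients is adult (>= 30
years at diagnosis), and the TCGA / single-institution source strata are
assigned with the adult bias observed in real compendia (TCGA is almost
entirely adult; institutional data almost entirely pediatric).

Planting utilities create the phenomena the downstream pipeline must
detect: per-focus-sample overexpression outliers placed a known effect above
the cohort Tukey threshold, genes whose spread is wider in the pediatric
stratum than the adult stratum (so per-cohort thresholds diverge while
medians agree), and gene-set collections in which one "supported pathway"
contains the planted genes.

All randomness flows from one explicit seed; identical seeds give
bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .compendium import ExpressionCompendium, GeneSetCollection, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating/planting a synthetic compendium."""

    planted_outliers: Dict[str, Dict[str, float]] = field(default_factory=dict)
    divergent_genes: Set[str] = field(default_factory=set)
    disease_assignments: Dict[str, str] = field(default_factory=dict)
    expected_neighbors: Dict[str, Set[str]] = field(default_factory=dict)
    druggable_genes: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "planted_outliers": {
                f: dict(sorted(genes.items())) for f, genes in sorted(self.planted_outliers.items())
            },
            "divergent_genes": sorted(self.divergent_genes),
            "disease_assignments": dict(sorted(self.disease_assignments.items())),
            "expected_neighbors": {
                s: sorted(n) for s, n in sorted(self.expected_neighbors.items())
            },
            "druggable_genes": sorted(self.druggable_genes),
        }


def generate_compendium(
    n_genes: int,
    n_samples: int,
    n_diseases: int,
    adult_fraction: float,
    tcga_fraction: float,
    seed: int,
    noise_sd: float = 1.0,
    disease_effect_sd: float = 1.5,
    base_expression_range: Tuple[float, float] = (2.0, 10.0),
    institution_share: float = 0.3,
    tcga_adult_weight: float = 25.0,
    druggable_fraction: float = 0.05,
) -> Tuple[ExpressionCompendium, SyntheticTruth]:
    """Generate a compendium with disease-driven correlation structure.

    Expression for sample s of disease d at gene g is

        clip( base_g + delta_{d,g} + eps_{s,g}, 0 )

    with base_g ~ U(base_low, base_high) shared by every disease,
    delta_{d,g} ~ N(0, disease_effect_sd^2) the disease signature and
    eps ~ N(0, noise_sd^2) sample noise.  Because the disease signature is
    shared within a disease and independent between diseases, within-disease
    pairwise Spearman correlation exceeds between-disease correlation in
    expectation, giving neighbor discovery real signal.

    ``druggable_fraction`` of genes are marked as the synthetic druggable
    genome (recorded in the truth object; planting utilities draw from it).
    """
    if n_samples < 2 * n_diseases:
        raise ValueError(
            f"need n_samples >= 2*n_diseases to give every disease >= 2 samples "
            f"(got {n_samples} samples for {n_diseases} diseases)"
        )
    for name, frac in (("adult_fraction", adult_fraction), ("tcga_fraction", tcga_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    if n_diseases < 1 or n_genes < 1:
        raise ValueError("n_genes and n_diseases must be >= 1")

    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    diseases = [f"disease_{i:02d}" for i in range(n_diseases)]

    # Disease assignment: two guaranteed samples per disease, remainder uniform.
    assignment = np.array(
        list(np.repeat(np.arange(n_diseases), 2))
        + list(rng.integers(0, n_diseases, n_samples - 2 * n_diseases))
    )
    rng.shuffle(assignment)

    base = rng.uniform(*base_expression_range, size=n_genes)
    disease_profiles = base[None, :] + rng.normal(0.0, disease_effect_sd, (n_diseases, n_genes))
    noise = rng.normal(0.0, noise_sd, (n_samples, n_genes))
    values = np.clip(disease_profiles[assignment] + noise, 0.0, None).T  # genes x samples

    # Ages: requested adult share, pediatric strictly below 30.
    n_adult = int(round(adult_fraction * n_samples))
    adult_idx = rng.choice(n_samples, size=n_adult, replace=False)
    is_adult = np.zeros(n_samples, dtype=bool)
    is_adult[adult_idx] = True
    ages = np.where(
        is_adult,
        rng.uniform(30.0, 80.0, n_samples),
        rng.uniform(0.0, 29.99, n_samples),
    )

    # Sources: TCGA drawn with a strong adult bias, mirroring real compendia
    # in which TCGA is >96% adult and institutional data mostly pediatric.
    n_tcga = int(round(tcga_fraction * n_samples))
    weights = np.where(is_adult, tcga_adult_weight, 1.0)
    source = np.array(["other"] * n_samples, dtype=object)
    if n_tcga > 0:
        tcga_idx = rng.choice(n_samples, size=n_tcga, replace=False, p=weights / weights.sum())
        source[tcga_idx] = "tcga"
    non_tcga = np.flatnonzero(source != "tcga")
    inst_mask = rng.random(len(non_tcga)) < institution_share
    source[non_tcga[inst_mask]] = "institution"

    metadata = [
        SampleMetadata(
            sample_id=samples[i],
            disease=diseases[assignment[i]],
            age_at_diagnosis=float(round(ages[i], 2)),
            source=str(source[i]),
            qc_status="pass",
        )
        for i in range(n_samples)
    ]
    c = ExpressionCompendium(pd.DataFrame(values, index=genes, columns=samples), metadata)

    n_druggable = max(1, int(round(druggable_fraction * n_genes)))
    druggable = sorted(rng.choice(genes, size=n_druggable, replace=False).tolist())

    by_disease: Dict[str, List[str]] = {d: [] for d in diseases}
    for i, s in enumerate(samples):
        by_disease[diseases[assignment[i]]].append(s)
    truth = SyntheticTruth(
        disease_assignments={s: diseases[assignment[i]] for i, s in enumerate(samples)},
        expected_neighbors={
            s: set(by_disease[diseases[assignment[i]]]) - {s} for i, s in enumerate(samples)
        },
        druggable_genes=druggable,
    )
    return c, truth


def plant_outliers(
    c: ExpressionCompendium,
    focus: str,
    genes: Iterable[str],
    effect: float,
    truth: Optional[SyntheticTruth] = None,
    background: Optional[Sequence[str]] = None,
) -> Tuple[ExpressionCompendium, SyntheticTruth]:
    """Overwrite the focus sample's expression of ``genes`` to sit ``effect``
    log2 units above the background cohort's Tukey threshold.

    The threshold is Q75 + 1.5*IQR of the gene over ``background`` (default:
    every sample except the focus), so downstream Tukey calling against that
    background recovers the planted genes by construction.  Only the
    (gene, focus) cells are touched.
    """
    if effect <= 0:
        raise ValueError(f"effect must be > 0 log2 units, got {effect}")
    if focus not in set(c.samples):
        raise KeyError(f"unknown focus sample {focus!r}")
    genes = list(genes)
    unknown = [g for g in genes if g not in set(c.genes)]
    if unknown:
        raise KeyError(f"unknown gene(s): {unknown}")
    if background is None:
        background = [s for s in c.samples if s != focus]
    else:
        background = [s for s in background if s != focus]
        if len(background) < 2:
            raise ValueError("background must contain >= 2 non-focus samples")

    out = c.copy()
    truth = truth if truth is not None else SyntheticTruth()
    planted = truth.planted_outliers.setdefault(focus, {})
    bg = out.values.loc[genes, background].to_numpy()
    q75 = np.quantile(bg, 0.75, axis=1)
    q25 = np.quantile(bg, 0.25, axis=1)
    thresholds = q75 + 1.5 * (q75 - q25)
    for g, thr in zip(genes, thresholds):
        out.values.at[g, focus] = float(thr) + effect
        planted[g] = effect
    return out, truth


def plant_cohort_divergent_gene(
    c: ExpressionCompendium,
    gene: str,
    pediatric_sd: float,
    adult_sd: float,
    seed: int,
    age_cutoff: float = 30.0,
    truth: Optional[SyntheticTruth] = None,
) -> ExpressionCompendium:
    """Redraw one gene so the pediatric stratum is wider than the adult one.

    Both strata are redrawn as Gaussians centred on the gene's current median
    (clipped at 0), so the strata share a median while the pediatric IQR --
    and hence any pediatric-containing cohort's Tukey threshold -- is larger.
    This reproduces the mechanism by which adult-only comparator cohorts call
    outliers that mixed cohorts do not.
    """
    if pediatric_sd <= adult_sd:
        raise ValueError(
            f"pediatric_sd must exceed adult_sd, got {pediatric_sd} <= {adult_sd}"
        )
    if gene not in set(c.genes):
        raise KeyError(f"unknown gene {gene!r}")
    if c.metadata is None:
        raise ValueError("compendium metadata (ages) required to stratify samples")

    rng = np.random.default_rng(seed)
    out = c.copy()
    center = float(np.median(out.values.loc[gene].to_numpy()))
    for s in out.samples:
        age = out.metadata[s].age_at_diagnosis
        if age is None:
            continue
        sd = pediatric_sd if age < age_cutoff else adult_sd
        out.values.at[gene, s] = max(0.0, center + rng.normal(0.0, sd))
    if truth is not None:
        truth.divergent_genes.add(gene)
    return out


def generate_gene_sets(
    truth: SyntheticTruth,
    genes: Sequence[str],
    n_sets: int,
    seed: int,
    set_size: int = 25,
) -> GeneSetCollection:
    """Emit a gene-set collection with one planted "supported pathway".

    The first set contains every planted-outlier gene plus random members;
    the remaining ``n_sets - 1`` decoy sets are drawn from the non-planted
    genes only.  Deterministic given the seed.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    planted = sorted({g for genes_of in truth.planted_outliers.values() for g in genes_of})
    pool = [g for g in genes if g not in set(planted)]
    sets: Dict[str, frozenset] = {}
    pad = max(0, set_size - len(planted))
    filler = rng.choice(pool, size=min(pad, len(pool)), replace=False).tolist() if pad else []
    sets["SUPPORTED_PATHWAY"] = frozenset(planted + filler)
    for i in range(1, n_sets):
        members = rng.choice(pool, size=min(set_size, len(pool)), replace=False).tolist()
        sets[f"DECOY_SET_{i:03d}"] = frozenset(members)
    return GeneSetCollection(sets=sets, universe=frozenset(genes))


def generate_version_update_scenario(seed: int) -> dict:
    """Build paired compendium versions reproducing the compendium-update case.

    A focus sample's disease A has only two other samples in the old version,
    so its "diseases of the top-6 most correlated datasets" cohort spans three
    related diseases (A plus bridge samples from B and C), and a gene planted
    high in the focus is a consensus outlier (called by the first+second-degree
    and top-6-diseases cohorts).  The new version adds 95 high-quality disease-A
    samples whose expression of the planted gene is comparable to the focus:
    the top-6 list collapses to disease A alone, the same-disease and top-6
    cohorts no longer call the gene, and it survives only in the diluted
    first+second-degree cohort -- a consensus -> single-cohort flip.

    Returns a dict with c_old, c_new, focus, gene, params (with the similarity
    threshold overridden, as done for a fixed compendium version) and the
    engineered disease labels.
    """
    rng = np.random.default_rng(seed)
    n_genes = 3000
    genes = [f"G{i:05d}" for i in range(n_genes)]

    # Floor of 4 keeps zero-clipping negligible, so the engineered Spearman
    # separations between disease strata are not disturbed by ties at zero.
    base = rng.uniform(4.0, 10.0, n_genes)
    shared_core = rng.normal(0.0, 1.5, n_genes)  # shared by the three related diseases
    delta = {d: rng.normal(0.0, 0.4, n_genes) for d in ("A", "B", "C")}
    profile_d = base + rng.normal(0.0, 1.5, n_genes)  # unrelated disease

    def sample_values(disease: str, noise_sd: float) -> np.ndarray:
        if disease == "D":
            mean = profile_d
        else:
            mean = base + shared_core + delta[disease]
        return np.clip(mean + rng.normal(0.0, noise_sd, n_genes), 0.0, None)

    cols: Dict[str, np.ndarray] = {}
    meta: List[SampleMetadata] = []

    def add(sample_id: str, disease: str, noise_sd: float) -> None:
        cols[sample_id] = sample_values(disease, noise_sd)
        meta.append(
            SampleMetadata(
                sample_id=sample_id,
                disease={"A": "disease_a", "B": "disease_b", "C": "disease_c", "D": "disease_d"}[
                    disease
                ],
                age_at_diagnosis=10.0,
                source="other",
                qc_status="pass",
            )
        )

    focus = "FOCUS"
    add(focus, "A", 0.98)  # extra noise: the focus is an atypical disease-A sample
    for i in range(2):
        add(f"A_OLD_{i:02d}", "A", 0.6)
    # Bridge samples: low-noise B/C datasets slightly more correlated to the
    # focus than the bulk of B/C, so the old top-6 list spans three diseases.
    for i in range(2):
        add(f"B_BRIDGE_{i:02d}", "B", 0.43)
        add(f"C_BRIDGE_{i:02d}", "C", 0.43)
    for i in range(198):
        add(f"B_{i:03d}", "B", 0.6)
    for i in range(198):
        add(f"C_{i:03d}", "C", 0.6)
    for i in range(100):
        add(f"D_{i:03d}", "D", 0.6)

    values_old = pd.DataFrame(cols, index=genes)

    # Plant the finding gene: high in the focus, background-level elsewhere.
    gene = "G01500"
    gi = genes.index(gene)
    background_g = np.clip(rng.normal(3.0, 1.0, values_old.shape[1]), 0.0, None)
    values_old.iloc[gi, :] = background_g
    focus_g = 10.0
    values_old.at[gene, focus] = focus_g
    c_old = ExpressionCompendium(values_old, list(meta))

    # New version: 95 added disease-A samples with comparable expression of
    # the planted gene (the focus's level is no longer exceptional for A).
    new_cols: Dict[str, np.ndarray] = {}
    new_meta = list(meta)
    for i in range(95):
        sid = f"A_NEW_{i:02d}"
        v = sample_values("A", 0.6)
        v[gi] = max(0.0, focus_g + rng.normal(0.0, 0.5))
        new_cols[sid] = v
        new_meta.append(
            SampleMetadata(
                sample_id=sid,
                disease="disease_a",
                age_at_diagnosis=10.0,
                source="other",
                qc_status="pass",
            )
        )
    values_new = pd.concat([values_old, pd.DataFrame(new_cols, index=genes)], axis=1)
    c_new = ExpressionCompendium(values_new, new_meta)

    from .params import Parameters

    params = Parameters(similarity_threshold_override=0.872)
    return {
        "c_old": c_old,
        "c_new": c_new,
        "focus": focus,
        "gene": gene,
        "params": params,
        "focus_disease": "disease_a",
    }
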