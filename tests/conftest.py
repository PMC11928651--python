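import logging

import numpy as np
import pandas as pd
import pytest

import panoutlier as po

# planting/cohort warnings are expected noise in the suite
logging.getLogger("panoutlier").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_compendium():
    """200 genes x 60 samples, 3 diseases, balanced strata; session-scoped."""
    c, truth = po.generate_compendium(
        n_genes=200, n_samples=60, n_diseases=3, adult_fraction=0.5, tcga_fraction=0.5, seed=7
    )
    return c, truth


@pytest.fixture()
def tiny_matrix():
    """4 genes x 6 samples with hand-computable values."""
    values = pd.DataFrame(
        np.arange(24, dtype=float).reshape(4, 6),
        index=["GA", "GB", "GC", "GD"],
        columns=[f"S{i}" for i in range(6)],
    )
    return po.ExpressionCompendium(values)


def make_metadata(samples, diseases, ages=None, sources=None, qc=None):
    ages = ages or [10.0] * len(samples)
    sources = sources or ["other"] * len(samples)
    qc = qc or ["pass"] * len(samples)
    return [
        po.SampleMetadata(sample_id=s, disease=d, age_at_diagnosis=a, source=src, qc_status=q)
        for s, d, a, src, q in zip(samples, diseases, ages, sources, qc)
    ]
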