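"""Shared fixtures: small corpora and session-scoped fitted pipelines.

Heavy artifacts (trained embedding model, fitted end-to-end pipeline) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from mint.nn import MLPConfig
from mint.synth import make_benchmark

warnings.filterwarnings("ignore", category=FutureWarning)


def random_profile(rng: np.random.Generator):
    """A random valid nutrient profile (all 11 amounts present)."""
    from mint.nutrients import DEFAULT_DAILY_VALUES, NUTRIENTS, NutrientProfile

    return NutrientProfile(
        {
            k: float(DEFAULT_DAILY_VALUES[k] * rng.uniform(0.05, 3.0))
            for k in NUTRIENTS
        }
    )


@pytest.fixture(scope="session")
def benchmark_corpus():
    """Default synthetic benchmark: 4 categories x 500 items, seed 0."""
    return make_benchmark(seed=0)


@pytest.fixture(scope="session")
def small_corpus():
    """Cheap corpus for smoke-level pipeline tests."""
    return make_benchmark(seed=3, items_per_category=150)


@pytest.fixture(scope="session")
def mlp_config():
    return MLPConfig(dropout=0.1, patience=30, max_epochs=500)


@pytest.fixture(scope="session")
def fitted_benchmark(benchmark_corpus, mlp_config):
    """One end-to-end fit of the default benchmark (seed 0)."""
    from mint.workflow import fit_mint

    return fit_mint(benchmark_corpus, seed=0, mlp_config=mlp_config)


@pytest.fixture(scope="session")
def trained_embedding(benchmark_corpus):
    from mint.embeddings import train_embedding_model

    return train_embedding_model(
        benchmark_corpus.documents, dimension=48, epochs=4, seed=0
    )
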