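import numpy as np
import pandas as pd
import pytest

from cafrank import CountMatrix, NormalizedMatrix, SyntheticSpec, simulate_counts


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_genes=400, n_stage_unique=20, n_shared=10, seed=7)


@pytest.fixture(scope="session")
def small_counts(small_spec):
    counts, truth = simulate_counts(small_spec)
    return counts, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values, samples=None, groups=None) -> NormalizedMatrix:
    """Build a NormalizedMatrix from a 2-D array with default naming."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    groups = groups or ["A"] * n_samples
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)],
                      columns=samples)
    return NormalizedMatrix(values=df, design=pd.Series(groups, index=samples))


def make_counts(values, samples=None, groups=None) -> CountMatrix:
    values = np.asarray(values)
    n_genes, n_samples = values.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    groups = groups or ["A"] * n_samples
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)],
                      columns=samples)
    return CountMatrix(values=df, design=pd.Series(groups, index=samples))
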