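import numpy as np
import pandas as pd
import pytest

from cutspec.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def toy_counts():
    """2 genes x 3 samples, small enough to check by hand."""
    return pd.DataFrame(
        [[100, 10, 0], [900, 990, 500]],
        index=pd.Index(["G1", "G2"], name="gene_id"),
        columns=["S1", "S2", "S3"],
    )


@pytest.fixture
def toy_samples():
    return pd.DataFrame(
        {
            "region": ["X", "X", "Y"],
            "animal_id": ["a1", "a2", "a1"],
            "sex": ["M", "F", "M"],
        },
        index=pd.Index(["S1", "S2", "S3"], name="sample_id"),
    )


@pytest.fixture
def toy_lengths():
    return pd.Series(
        [1000, 2500],
        index=pd.Index(["G1", "G2"], name="gene_id"),
        name="length",
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 3-region simulation shared by pipeline-level tests."""
    cfg = SimulationConfig(
        n_regions=3, n_animals=4, n_genes=300, n_rsg_per_region=5, seed=7
    )
    return simulate_dataset(cfg)


def make_two_group_counts(rng, n_genes, n_per_group, baseline, alpha, fold_genes=None, fold=1.0):
    """NB counts for two groups A/B with optional planted fold in group A.

    Independent oracle-style generator used by DE tests: draws negative
    binomial directly from numpy, not through the package simulator.
    """
    mu = np.repeat(baseline[:, None], 2 * n_per_group, axis=1).astype(float)
    if fold_genes is not None:
        mu[fold_genes, :n_per_group] *= fold
    if alpha == 0:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / alpha
        counts = rng.negative_binomial(size, size / (size + mu))
    cols = [f"A_{i}" for i in range(n_per_group)] + [f"B_{i}" for i in range(n_per_group)]
    counts = pd.DataFrame(
        counts, index=pd.Index([f"G{i}" for i in range(n_genes)], name="gene_id"), columns=cols
    )
    samples = pd.DataFrame(
        {
            "region": ["A"] * n_per_group + ["B"] * n_per_group,
            "animal_id": [f"a{i}" for i in range(n_per_group)] * 2,
        },
        index=pd.Index(cols, name="sample_id"),
    )
    return counts, samples
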