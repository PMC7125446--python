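import numpy as np
import pandas as pd
import pytest

from mdgnet import simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_pair():
    """A 30-gene null cohort pair (10 vs 12 samples)."""
    return simulate.gen_null_pair(30, 10, 12, seed=101)


@pytest.fixture(scope="session")
def five_gene_matrix(rng):
    """5 genes x 9 samples with ties, for pairwise-correlation oracles."""
    values = rng.integers(0, 6, size=(5, 9)).astype(float)
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{j}" for j in range(9)],
    )


@pytest.fixture(scope="session")
def de_dataset_delta0():
    """All-branch dataset with zero location shift (routing fixture)."""
    config = simulate.SimConfig(
        n_genes=330,
        n_samples_c=64,
        n_samples_e=82,
        seed=77,
        de_block_sizes=(30, 30, 30, 30, 210),
        effect_size=0.0,
    )
    return simulate.gen_de_dataset(config)
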