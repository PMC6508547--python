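import numpy as np
import pandas as pd
import pytest

from jacatlas import sim


@pytest.fixture(scope="session")
def small_sim():
    """Small but complete factorial dataset with planted archetypes."""
    cfg = sim.SimConfig(n_genes=400, replicates=3, seed=7)
    counts, samples, truth = sim.simulate_counts(cfg)
    return cfg, counts, samples, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def toy_counts(rng, n_genes=20, n_samples=6, lam=50.0) -> pd.DataFrame:
    """Small all-positive Poisson matrix for normalization oracles."""
    values = rng.poisson(lam, size=(n_genes, n_samples)) + 1
    return pd.DataFrame(
        values,
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
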