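import numpy as np
import pandas as pd
import pytest

from nitronet import simulate


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    """3 taxa x 2 samples with easy hand arithmetic."""
    return pd.DataFrame(
        {"s1": [5, 3, 2], "s2": [1, 1, 8]}, index=["t1", "t2", "t3"]
    )


@pytest.fixture
def toy_taxonomy() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "domain": ["Bacteria"] * 4,
            "phylum": ["Proteobacteria", "Proteobacteria", "Actinobacteria", "Actinobacteria"],
            "class": ["c1", "c1", "c2", "c2"],
            "order": ["o1", "o1", "o2", "o2"],
            "family": ["f1", "f1", "f2", "f2"],
            "genus": ["Sphingomonas", "Sphingomonas", "Gaiella", "Nocardioides"],
        },
        index=["t1", "t2", "t3", "t4"],
    )


@pytest.fixture
def small_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(n_taxa=40, n_modules=4, depth=1500, seed=11)


@pytest.fixture
def block_correlation():
    """Block-structured correlation matrix factory: within 0.9, between 0.1,
    plus a small symmetric GOE jitter that breaks degeneracy."""

    def make(seed: int = 0, jitter: float = 0.04, n_taxa: int = 60, n_blocks: int = 5):
        block = np.arange(n_taxa) % n_blocks
        rho = np.where(block[:, None] == block[None, :], 0.9, 0.1)
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, jitter, (n_taxa, n_taxa))
        rho = rho + (noise + noise.T) / 2
        np.fill_diagonal(rho, 1.0)
        labels = [f"g{i:02d}" for i in range(n_taxa)]
        return pd.DataFrame(np.clip(rho, -1, 1), index=labels, columns=labels), block

    return make
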