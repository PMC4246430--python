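import numpy as np
import pandas as pd
import pytest

from sagesac.synthetic_data import SimulationConfig, simulate_dataset
from sagesac.tag_alignment import CountMatrix


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete truth-known dataset shared across tests."""
    cfg = SimulationConfig(n_genes=80, depth=4000, epsilon=0.0, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_count_matrix(counts: np.ndarray, days, genes=None) -> CountMatrix:
    """Helper to wrap an array into a CountMatrix with day metadata."""
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"{d}_s{j}" for j, d in enumerate(days)]
    meta = pd.DataFrame(
        {"sample_id": samples, "day": list(days),
         "replicate": list(range(1, len(days) + 1))}
    ).set_index("sample_id")
    df = pd.DataFrame(counts, index=genes, columns=samples)
    return CountMatrix(df, meta)
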