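import numpy as np
import pytest

from contamqc.feature_table import FeatureTable, SampleRecord
from contamqc.synthetic import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One default-condition simulated study shared across tests."""
    return simulate_study(SimulationConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_table():
    counts = np.array(
        [
            [5, 0, 3, 1],
            [0, 2, 0, 0],
            [1, 1, 1, 1],
        ]
    )
    return FeatureTable(["t1", "t2", "t3"], ["s1", "s2", "s3", "s4"], counts)


@pytest.fixture()
def two_batch_metadata():
    recs = []
    for i, b in enumerate(["batch1", "batch1", "batch2", "batch2"]):
        recs.append(SampleRecord(f"s{i + 1}", b, f"run{b[-1]}.1", "biological", 1.0 + i))
    return recs


def random_table(rng, n_taxa=30, n_samples=40, max_count=50):
    counts = rng.integers(0, max_count, size=(n_taxa, n_samples))
    return FeatureTable(
        [f"t{i}" for i in range(n_taxa)],
        [f"s{j}" for j in range(n_samples)],
        counts,
    )
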