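import numpy as np
import pandas as pd
import pytest

from twocolorqc import ExpressionMatrix, SimConfig, build_matrix, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Generator output at default study conditions (desk scale)."""
    cfg = SimConfig(seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_matrices(default_dataset):
    m3, _ = build_matrix(default_dataset.tables, "Cy3")
    m5, _ = build_matrix(default_dataset.tables, "Cy5")
    return m3, m5


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SimConfig(n_probes=400, n_replicate_probes=40, n_arrays=6, seed=5)
    return generate_dataset(cfg)


def random_matrix(n_probes, n_arrays, seed, channel="Cy3", loc=8.0, scale=1.5):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        rng.normal(loc, scale, size=(n_probes, n_arrays)),
        index=[f"P{i:05d}" for i in range(n_probes)],
        columns=[f"array{j:03d}" for j in range(n_arrays)],
    )
    return ExpressionMatrix(data, channel=channel)
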