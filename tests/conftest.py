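import numpy as np
import pandas as pd
import pytest

import tempoclust as tc


@pytest.fixture(scope="session")
def planted():
    """Default 5-archetype simulation (1000 genes, T=6, R=3) with truth."""
    cfg = tc.default_config(seed=11)
    ds, truth = tc.simulate_timecourse(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def np_view(planted):
    _, ds, _ = planted
    return tc.normalized_profiles(tc.average_replicates(ds))


@pytest.fixture(scope="session")
def fc_view(planted):
    _, ds, _ = planted
    return tc.fold_change_profiles(tc.average_replicates(ds), "producer", "control")


@pytest.fixture()
def tiny_dataset():
    """Two conditions x two replicates, four genes, hand-checkable values."""
    values = pd.DataFrame(
        {
            "a1": [1.0, 0.0, 5.0, 2.0],
            "a2": [3.0, 0.0, 5.0, 2.0],
            "b1": [4.0, 1.0, 5.0, 8.0],
            "b2": [6.0, 1.0, 5.0, 8.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    meta = pd.DataFrame(
        {
            "strain": ["producer", "producer", "control", "control"],
            "time_h": [47.0, 47.0, 47.0, 47.0],
            "replicate": [1, 2, 1, 2],
        },
        index=values.columns,
    )
    return tc.ExpressionDataset(values=values, metadata=meta)


def make_dataset(values: np.ndarray, n_a: int, n_b: int) -> tc.ExpressionDataset:
    """Wrap a gene x (n_a + n_b) array as a producer/control single-time dataset."""
    samples = [f"p{i}" for i in range(n_a)] + [f"c{i}" for i in range(n_b)]
    meta = pd.DataFrame(
        {
            "strain": ["producer"] * n_a + ["control"] * n_b,
            "time_h": [47.0] * (n_a + n_b),
            "replicate": list(range(1, n_a + 1)) + list(range(1, n_b + 1)),
        },
        index=samples,
    )
    genes = [f"g{i}" for i in range(len(values))]
    return tc.ExpressionDataset(pd.DataFrame(values, index=genes, columns=samples), meta)
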