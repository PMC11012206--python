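import numpy as np
import pytest

from spectrafuse.datasets import SpectralDataset
from spectrafuse.synthetic import SyntheticConfig, split_signal_config


@pytest.fixture
def toy_dataset() -> SpectralDataset:
    """3 samples x 4 variables, hand-written."""
    return SpectralDataset(
        values=np.array([
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 4.0, 6.0, 8.0],
            [1.5, 2.0, 2.5, 3.0],
        ]),
        axis=np.array([200.0, 210.0, 220.0, 230.0]),
        units="nm",
        sample_ids=np.array(["a", "b", "c"], dtype=object),
        labels=np.array(["north", "north", "south"], dtype=object),
    )


@pytest.fixture
def tiny_config() -> SyntheticConfig:
    """Small, fast cohort on coarse grids for contract tests (the full
    225-sample study-design cohort is exercised where sizes matter)."""
    from dataclasses import replace

    return replace(
        split_signal_config(seed=7),
        class_sizes=(8, 8, 8, 8, 8),
        uv_axis=(190.0, 700.0, 10.0),
        mir_axis=(400.0, 4000.0, 50.0),
    )


def make_separable_dataset(n_per_class=10, n_vars=6, gap=5.0, seed=0):
    """Two classes separated cleanly in variable 0, noise elsewhere."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    values = rng.normal(0, 1, (n, n_vars))
    labels = np.array(["A"] * n_per_class + ["B"] * n_per_class, dtype=object)
    values[:n_per_class, 0] = rng.normal(-gap, 0.1, n_per_class)
    values[n_per_class:, 0] = rng.normal(gap, 0.1, n_per_class)
    return SpectralDataset(
        values=values,
        axis=np.arange(n_vars, dtype=float) + 100.0,
        units="nm",
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        labels=labels,
    )
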