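import numpy as np
import pandas as pd
import pytest

from bdcp import DataSet, ModelSpec


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


def make_table(n: int, n_cov: int, seed: int, beta=None, sigma: float = 2.0) -> pd.DataFrame:
    """Small Gaussian linear dataset as a rectangular table (y + x2, x3, ...)."""
    r = np.random.default_rng(seed)
    Z = r.normal(0.0, 3.0, size=(n, n_cov))
    if beta is None:
        beta = np.ones(n_cov)
    y = 1.0 + Z @ np.asarray(beta, dtype=float) + r.normal(0.0, sigma, size=n)
    cols = [f"x{i}" for i in range(2, n_cov + 2)]
    frame = pd.DataFrame(Z, columns=cols)
    frame.insert(0, "y", y)
    return frame


@pytest.fixture()
def small_data() -> DataSet:
    """n=30 dataset with three covariates; plenty of signal, no degeneracy."""
    return DataSet.from_frame(make_table(30, 3, seed=7), response="y")


@pytest.fixture()
def nested_specs():
    return ModelSpec(("x2",)), ModelSpec(("x2", "x3", "x4"))
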