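import numpy as np
import pandas as pd
import pytest

from eustex import correlation_pair, cohort_feature_table


def make_gaussian_table(n_per_class: int, n_noise: int, n_informative: int = 0,
                        separation: float = 3.0, seed: int = 0,
                        prefix: str = "f") -> pd.DataFrame:
    """Cohort table of Gaussian features: informative columns first.

    Informative features shift their mean by ``separation`` between classes;
    noise features are iid standard normal in both classes.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    labels = np.array([1] * n_per_class + [0] * n_per_class)
    cols = {}
    for i in range(n_informative):
        x = rng.standard_normal(n)
        x[labels == 1] += separation
        cols[f"{prefix}_info{i}"] = x
    for i in range(n_noise):
        cols[f"{prefix}_noise{i}"] = rng.standard_normal(n)
    df = pd.DataFrame(cols)
    df.insert(0, "label", labels)
    df.insert(0, "case_id", [f"c{i:03d}" for i in range(n)])
    return df


@pytest.fixture(scope="session")
def speckle_table() -> pd.DataFrame:
    """Small separable synthetic-speckle cohort (correlation length 2 vs 6)."""
    pc, cp = correlation_pair(2.0, 6.0)
    return cohort_feature_table(pc, cp, 15, 15, size=(32, 32), seed=11)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
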