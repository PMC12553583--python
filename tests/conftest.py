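import numpy as np
import pandas as pd
import pytest

from contamdrivers.preprocess import AnnualSeries
from contamdrivers.synthetic_data import SyntheticConfig, generate_fish, \
    generate_predictors


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def years():
    return np.arange(1995, 2019)


@pytest.fixture
def piecewise_series(years):
    """Noiseless vertex break at 2007: slope +1 before, -1 after."""
    vals = 1.0 * (years - 1995) - 2.0 * np.clip(years - 2007, 0, None)
    return AnnualSeries("piecewise", years, vals.astype(float))


@pytest.fixture
def small_config():
    return SyntheticConfig(seed=7, n_fish_per_year=8,
                           trend_slopes=(0.05,) * 14,
                           true_coefficients={"pred01": 0.2},
                           noise_sd=0.1)


@pytest.fixture
def synthetic_bundle(small_config):
    X, truth = generate_predictors(small_config)
    fish = generate_fish(small_config, X, truth)
    return small_config, X, truth, fish


def recovery_config(seed: int) -> SyntheticConfig:
    """The driver-recovery setup used by the acceptance suite: 14 predictors,
    three equal-magnitude true drivers, one acting at lag 1."""
    return SyntheticConfig(
        seed=seed,
        trend_slopes=(0.02,) * 14,
        true_coefficients={"pred03": 0.15, "pred07": -0.15, "pred11": 0.15},
        true_lags={"pred11": 1},
        noise_sd=0.04,
        predictor_noise_sd=1.0,
    )
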