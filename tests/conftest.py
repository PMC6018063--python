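import numpy as np
import pandas as pd
import pytest

from bgregime import DailySeries, FitConfig, RegimeSpec, simulate_hmm_series


def make_daily(values, year=2015, **kw) -> DailySeries:
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(f"{year}-01-01", periods=len(values), freq="D")
    return DailySeries(dates, values, **kw)


@pytest.fixture
def cfg() -> FitConfig:
    return FitConfig(seed=0)


@pytest.fixture
def two_regime_series():
    """A persistent, well-separated 2-state Markov-switching year."""
    spec = RegimeSpec(
        k_true=2,
        means=(10.0, 40.0),
        sds=(3.0, 3.0),
        transition=((0.95, 0.05), (0.05, 0.95)),
        seed=7,
    )
    ds, states = simulate_hmm_series(spec)
    return ds, states


@pytest.fixture
def gaussian_series():
    """365 i.i.d. draws from one Gaussian (no regime structure)."""
    rng = np.random.default_rng(11)
    return make_daily(rng.normal(30.0, 5.0, 365))
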