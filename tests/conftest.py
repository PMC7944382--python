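import numpy as np
import pandas as pd
import pytest

from emanet.ema_data import EmaSeries
from emanet.synthetic_cohort import CohortConfig, calibrate_intercept, generate_cohort


def make_series(pid, values, n_scheduled=None, answered=None):
    """Build an EmaSeries from a list of desire values (None = unanswered prompt)."""
    n = len(values)
    if answered is None:
        answered = [v is not None for v in values]
    desire = [np.nan if v is None else float(v) for v in values]
    records = pd.DataFrame({
        "prompt_index": np.arange(n),
        "timestamp": pd.date_range("2016-01-01 09:00", periods=n, freq="3h"),
        "answered": answered,
        "desire": desire,
        "intent": desire,
        "resist_urge": [np.nan if v is None else 9.0 - v for v in desire],
    })
    return EmaSeries(str(pid), records, n_scheduled=n_scheduled or n)


@pytest.fixture(scope="session")
def toy_series():
    """The worked-example series 0,0,9,9,0."""
    return make_series("T01", [0, 0, 9, 9, 0])


@pytest.fixture(scope="session")
def small_cohort():
    """A calibrated ~60-participant synthetic cohort, shared across tests."""
    config = calibrate_intercept(CohortConfig(n_participants=60, seed=1234))
    return generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_260_930)
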