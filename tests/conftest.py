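import numpy as np
import pandas as pd
import pytest

from bdews import ActivitySeries, CircadianParams, generate_circadian_series

MINUTES_PER_DAY = 1440


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def pure_24h_window():
    """One noiseless 7-day window of a 1440-min cosine around a positive mesor."""
    t = np.arange(7 * MINUTES_PER_DAY, dtype=float)
    return 100.0 + 80.0 * np.cos(2 * np.pi * t / MINUTES_PER_DAY)


@pytest.fixture
def quiet_params():
    """Small, fast baseline generator config with a clear 24-h rhythm."""
    return CircadianParams(n_days=14, mesor=100.0, amplitude=80.0, noise_sd=20.0, seed=42)


@pytest.fixture
def quiet_series(quiet_params):
    return generate_circadian_series(quiet_params)


def make_series(counts, mask=None, patient_id="t"):
    return ActivitySeries(
        patient_id=patient_id,
        start_time=pd.Timestamp("2020-01-06"),
        counts=np.asarray(counts, dtype=float),
        valid_mask=mask,
    )
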