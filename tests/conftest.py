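import numpy as np
import pandas as pd
import pytest

from ei_hrv import INDEX_NAMES, HrvTimeSeries, RrGenSpec, generate_rr_series, rr_from_peaks


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def uniform_rr():
    """800 ms beats spanning exactly 0–360 s (451 beats)."""
    return rr_from_peaks(np.round(np.arange(0, 360.0 + 0.4, 0.8), 10))


@pytest.fixture
def modulated_rr():
    """Tachogram 800 + 50 sin(2*pi*0.25 t) ms over 360 s, noise-free."""
    return generate_rr_series(
        RrGenSpec(mean_rr=800, modulations=((50.0, 0.25, 0.0),), noise_sd=0.0, duration=360)
    )


def make_window_series(values_by_index: dict, window: float = 180.0, step: float = 10.0,
                       t0: float = 90.0) -> HrvTimeSeries:
    """Build an HrvTimeSeries whose columns are constant or given sequences."""
    n = max(len(np.atleast_1d(v)) for v in values_by_index.values()) if values_by_index else 1
    data = {}
    for name in INDEX_NAMES:
        v = np.atleast_1d(values_by_index.get(name, 0.0)).astype(float)
        data[name] = np.resize(v, n)
    centers = t0 + step * np.arange(n)
    frame = pd.DataFrame(data, index=pd.Index(centers, name="window_center_s"))
    return HrvTimeSeries(frame=frame, window_length=window, step=step)
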