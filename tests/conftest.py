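import numpy as np
import pytest

from pivotwdi.met import MetRecord
from pivotwdi.synth import NoiseConfig, simulate_season
from pivotwdi.trapezoid import SurfaceParams


@pytest.fixture(scope="session")
def surface_params():
    return SurfaceParams()


@pytest.fixture
def midday_record():
    """A hot, dry, windy midday state typical of the study region."""
    return MetRecord(ta_c=32.0, rh_pct=30.0, rs_wm2=650.0, wind_ms=3.0)


@pytest.fixture(scope="session")
def zero_noise_season():
    """Default synthetic season with noiseless sensors (round-trip fixture)."""
    return simulate_season(7, noise=NoiseConfig(sigma_ts_c=0.0, sigma_ndvi=0.0))


@pytest.fixture(scope="session")
def noisy_season():
    """Default synthetic season at the default sensor noise levels."""
    return simulate_season(11)


def sample_met_states(n: int, seed: int = 0):
    """Property sample of midday meteorological states over the stated ranges
    (Ta 15-42 degC, RH 10-90%, Rs 100-900 W/m2, u2 0.5-8 m/s), with the
    clear-sky fraction tied to Rs for longwave consistency."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        rs = float(rng.uniform(100.0, 900.0))
        rec = MetRecord(ta_c=float(rng.uniform(15.0, 42.0)),
                        rh_pct=float(rng.uniform(10.0, 90.0)),
                        rs_wm2=rs,
                        wind_ms=float(rng.uniform(0.5, 8.0)))
        clearness = float(np.clip(rs / 950.0, 0.3, 1.0))
        out.append((rec, clearness))
    return out
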