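import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tbprobe.calibration import CalibrationModel
from tbprobe.probing import ProbeProfile

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_profile(samples, delta_d=0.15, d_tb=None, grid_xy=(0.0, 0.0)):
    """Build a ProbeProfile directly from a sample sequence.

    By default d_TB is taken consistent with the sample count
    (samples span [0, d_TB] at delta_d steps)."""
    samples = np.asarray(samples, dtype=float)
    if d_tb is None:
        d_tb = (len(samples) - 1) * delta_d
    return ProbeProfile(grid_xy=grid_xy, status="ok", samples=samples,
                        delta_d=delta_d, d_tb=float(d_tb))


def random_profiles(n, rng, delta_d=0.15):
    """Random synthetic HU profiles spanning air to dense cortical bone."""
    out = []
    for _ in range(n):
        m = int(rng.integers(2, 122))  # d_TB in (0.15, 18.15) mm
        samples = rng.uniform(-1000.0, 2500.0, size=m)
        out.append(make_profile(samples, delta_d=delta_d))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20210930)


@pytest.fixture
def calib_model():
    return CalibrationModel(slope=1.32, intercept=0.0)
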