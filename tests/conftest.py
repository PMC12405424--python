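import numpy as np
import pytest

from canopylight.cli_io import growth_stages, published_coefficients
from canopylight.illumination_model import PolyCoefficients, StageParams

#: Observed (h, theta) pairs, one per growth stage.
STAGE_GRID = [(5, 33.8), (23, 30.4), (113, 27.0), (101, 21.4), (100, 13.9)]
#: Full-rank calibration grid: cross product of the observed h and theta
#: values with the instrumented row positions.  (The five paired stage
#: points alone cannot identify all six (h, theta) surface terms.)
H_VALUES = [5, 23, 100, 101, 113]
THETA_VALUES = [13.9, 21.4, 27.0, 30.4, 33.8]
ROW_POSITIONS = [30, 60, 90, 120, 150, 180]


@pytest.fixture(scope="session")
def coeffs():
    return published_coefficients()


@pytest.fixture(scope="session")
def stages():
    return growth_stages()


@pytest.fixture(scope="session")
def podding_stage(stages):
    return stages["podding"]


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def random_image(rng):
    def make(height=8, width=12, lo=0, hi=256, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return r.integers(lo, hi, size=(height, width, 3), dtype=np.int64).astype(np.uint8)

    return make


@pytest.fixture
def flat_profile_setup():
    """Coefficients and stage giving a strictly constant positive prediction."""
    return PolyCoefficients((42.0,) + (0.0,) * 9), StageParams(
        height_difference_cm=50, solar_elevation_deg=30
    )
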