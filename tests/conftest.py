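import numpy as np
import pytest

from larvadrift.grids import Grid
from larvadrift.probe_data import RegionBounds
from larvadrift.synthetic_fixtures import AnalyticFieldSpec, study_like_gyre


@pytest.fixture
def rng():
    return np.random.default_rng(20110808)


@pytest.fixture
def small_region():
    return RegionBounds(160.0, 163.0, -12.0, -9.0)


@pytest.fixture
def small_grid(small_region):
    # ~30x30 nodes at the native 0.1 deg spacing
    return Grid(small_region, spacing_deg=0.1)


@pytest.fixture
def rotation_spec(small_region):
    return AnalyticFieldSpec(
        "solid_rotation", {"center": (161.5, -10.5), "omega_per_day": 0.02}
    )


@pytest.fixture
def gyre_spec(small_region):
    return study_like_gyre(small_region)


@pytest.fixture
def uniform_spec():
    return AnalyticFieldSpec("uniform", {"u1": 0.05, "u2": 0.02})
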