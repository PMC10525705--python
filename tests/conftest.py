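import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lssdmap import make_tube

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def circle_tube():
    """Circular tube r=50 mm, 10 slices at 3 mm spacing."""
    return make_tube("circle", center=(0.0, 0.0), radii=50.0, z_range=(0.0, 27.0),
                     slice_spacing=3.0, label="Heart")


@pytest.fixture
def ellipse_tube():
    """Elliptical tube (a=40, b=25) mm, 4 slices, vertices off sector boundaries."""
    return make_tube("ellipse", center=(5.0, -3.0), radii=(40.0, 25.0),
                     z_range=(0.0, 9.0), slice_spacing=3.0, label="LV", phase_deg=3.7)


@pytest.fixture
def rng():
    return np.random.default_rng(20230913)
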