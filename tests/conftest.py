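import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gliaquant import synthetic as syn

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ellipse_geom():
    """A medium ellipse cell (pixel 0.1 µm) shared by detection tests."""
    return syn.gen_cell_mask(
        {"kind": "ellipse", "a": 110, "b": 90, "angle": 0.0},
        image_size=256,
        pixel_size=0.1,
        seed=1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
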