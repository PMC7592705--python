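import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from paloss.simulate import LandscapeConfig, generate_scene

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_scene(tmp_path_factory):
    """A 64x64 scene with overlapping PAs and every special record type."""
    cfg = LandscapeConfig(grid_rows=64, grid_cols=64, seed=7, n_pas=6, p_overlap=0.5)
    return generate_scene(cfg, tmp_path_factory.mktemp("scene64"))


@pytest.fixture(scope="session")
def clean_scene(tmp_path_factory):
    """A 96x96 scene with only valid PA records (no marine/proposed/point)."""
    cfg = LandscapeConfig(
        grid_rows=96,
        grid_cols=96,
        seed=11,
        n_pas=4,
        p_overlap=0.5,
        frac_marine=0.0,
        frac_proposed=0.0,
        frac_point=0.0,
        frac_missing_year=0.0,
    )
    return generate_scene(cfg, tmp_path_factory.mktemp("scene96"))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
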