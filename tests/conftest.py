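import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mxif3d import PhantomConfig, generate_phantom  # noqa: E402


@pytest.fixture(scope="session")
def small_phantom():
    """Unwarped 5-section phantom with moderate density, shared read-only."""
    cfg = PhantomConfig(
        n_sections=5,
        image_shape=(160, 200),
        seed=13,
        affine_jitter=(0.0, 0.0),
        deform_max_px=0.0,
        cell_density_per_type={
            "Thelper": 15,
            "Tkiller": 5,
            "macrophage": 6,
            "endothelial": 6,
            "epithelial": 10,
        },
        vessel_count=2,
    )
    sections, truth = generate_phantom(cfg)
    return cfg, sections, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
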