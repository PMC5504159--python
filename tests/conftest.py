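import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ftilt import AcquisitionGeometry, generate_schedule


@pytest.fixture
def small_geometry():
    """Tiny joint grid: 16-point t1 over 100 Hz, 20 delays, 8x8 recon."""
    return AcquisitionGeometry(
        n_t1=16, sw_indirect=100.0, trelax_min=0.01, trelax_max=0.2,
        trelax_mesh=0.01, n_f1_recon=8, n_r_recon=8, r_min=0.5, r_max=5.0,
    )


@pytest.fixture
def medium_geometry():
    """Mid-size grid for recovery tests: 32-point t1, 32x16 recon."""
    return AcquisitionGeometry(
        n_t1=32, sw_indirect=200.0, trelax_min=0.01, trelax_max=0.4,
        trelax_mesh=0.01, n_f1_recon=32, n_r_recon=16, r_min=0.5, r_max=5.0,
    )


@pytest.fixture
def small_schedule(small_geometry):
    return generate_schedule(small_geometry, 24, seed=7)
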