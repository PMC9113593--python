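import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hcmb3 import rng  # noqa: E402

# Table 4 of the eye-data analysis: parameter estimates of the eight methods,
# used as fixed inputs for the circular-characteristics checks.
TABLE4_PARAMS = {
    "ADE": (2.044690, 8.364370, 2.703020),
    "RTADE": (1.353820, 7.036390, 0.790281),
    "CVME": (1.595240, 7.927040, 1.407220),
    "LSE": (1.560780, 7.734630, 1.342880),
    "MLE": (2.697290, 6.649040, 6.283080),
    "PCE": (5.726210, 7.437220, 19.17870),
    "MPSE": (2.507843, 5.818691, 5.982744),
    "WLSE": (1.632090, 7.915530, 1.513830),
}


@pytest.fixture(scope="session")
def sample_234():
    """Seeded n=500 sample from hcMB-III(2, 3, 4)."""
    return rng(500, (2.0, 3.0, 4.0), seed=42)


@pytest.fixture(scope="session")
def sample_small():
    """Seeded n=60 sample from hcMB-III(1, 3.5, 1)."""
    return rng(60, (1.0, 3.5, 1.0), seed=7)
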