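import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nailhgb as nh

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return nh.ForwardModelParams()


@pytest.fixture(scope="session")
def noiseless_params(params):
    return params.noiseless()


@pytest.fixture(scope="session")
def true_rgb_model(params):
    """Analytic inverse of the forward model on the RGB feature schema."""
    C, W = nh.true_model_coefficients(params, nh.RGB_SCHEMA)
    return nh.HgbModel(constant=C, weights=W, schema=nh.RGB_SCHEMA)


def grid_hgb(offsets):
    """Hgb values whose noiseless nailbed red lands exactly on the 8-bit grid
    (red slope 5.5/g/dL: offsets are integer red-units around 12 g/dL)."""
    return [12.0 + k / 5.5 for k in offsets]


@pytest.fixture(scope="session")
def small_clean_cohort(params):
    """12 artifact-free subjects with full noise, flash-on and flash-off."""
    return list(nh.iter_cohort(12, params=params, rng_seed=3))
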