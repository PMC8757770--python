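import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cddmclass import synthetic
from cddmclass.core import CDDM

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged default synthetic cohort (40 maps × 14 groups)."""
    return synthetic.generate_maps(synthetic.default_config())


@pytest.fixture(scope="session")
def clean_reference():
    """Small well-separated, nearly noise-free reference: 7 maps per group
    (enough training maps for the largest registry k of 12 in any duel)."""
    config = synthetic.default_config(
        separation=1.0,
        magnitude_noise_sd=0.005,
        angle_noise_sd=0.01,
        per_group_count=7,
        seed=7,
    )
    return synthetic.generate_maps(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_cddm(rng, h=10, w=10, label=None, map_id="x"):
    """A valid random map: positive magnitudes, angles in (−π, π]."""
    mag = rng.uniform(0.05, 1.0, (h, w))
    ang = rng.uniform(-np.pi, np.pi, (h, w))
    return CDDM(magnitude=mag, angle=ang, label=label, map_id=map_id)
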