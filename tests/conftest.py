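import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from reefcmr import StudyDesign


@pytest.fixture
def full_design():
    """The field-study window: May 2016 .. Nov 2019 (8 primaries, 43 months)."""
    return StudyDesign.from_window("2016-05", "2019-11")


@pytest.fixture
def small_design():
    """3 primaries x 2 secondaries: small enough for path enumeration."""
    return StudyDesign.regular("2016-05", 3, 2)


@pytest.fixture
def rng():
    return np.random.default_rng(20160501)


def random_interior_params(layout, rng, scale=1.2):
    """Random interior parameters on the logit scale for a layout."""
    return layout.expand(rng.normal(0.0, scale, layout.n_par))


def random_histories(rng, n_ind, n_occ):
    """Random binary histories, each with at least one detection."""
    h = rng.integers(0, 2, size=(n_ind, n_occ), dtype=np.int8)
    empty = h.sum(axis=1) == 0
    for i in np.nonzero(empty)[0]:
        h[i, rng.integers(0, n_occ)] = 1
    return h
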