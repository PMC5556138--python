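import numpy as np
import pytest
from hypothesis import settings

from twimsccs import ForwardModelSpec, Structure, gen_calibrant_set

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture
def noise_free_spec():
    return ForwardModelSpec(X_true=0.55, ln_A_true=6.0, c_edc=1.57, seed=11)


@pytest.fixture
def noise_free_calibrants(noise_free_spec):
    return gen_calibrant_set(noise_free_spec)


def make_sphere(radius: float, centre=(0.0, 0.0, 0.0)) -> Structure:
    """A single hard sphere as a one-atom structure with assigned radius."""
    return Structure("sphere", ["C"], np.array([centre], dtype=float),
                     radii=np.array([radius]))


def make_spheres(centres, radius: float) -> Structure:
    centres = np.asarray(centres, dtype=float)
    return Structure("spheres", ["C"] * len(centres), centres,
                     radii=np.full(len(centres), radius))
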