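import math

import numpy as np
import pytest

import saxskit as sk

SPHERE_R = 30.0
SPHERE_RG = math.sqrt(3.0 / 5.0) * SPHERE_R  # 23.2379...


@pytest.fixture(scope="session")
def sphere_model():
    """~2000-bead discretization of a homogeneous 30-A sphere."""
    return sk.generate_shape(sk.ShapeSpec(kind="sphere", n_beads=2000, radius=SPHERE_R), seed=7)


@pytest.fixture(scope="session")
def sphere_profile(sphere_model):
    """Noise-free Debye curve of the sphere on the default S grid."""
    return sk.debye_profile(sphere_model, sk.default_s_grid())


@pytest.fixture(scope="session")
def tandem_model():
    """Four-domain chain emulating a multidomain monomer (straight state)."""
    return sk.generate_shape(sk.ShapeSpec(kind="tandem", n_beads=600), seed=1)


@pytest.fixture(scope="session")
def bent_tandem_model():
    """Same chain bent 30 degrees at the central hinge (light-state mimic)."""
    return sk.generate_shape(
        sk.ShapeSpec(kind="tandem", n_beads=600, hinge_angle=30.0), seed=1
    )


def low_res_profile(model, s_max=0.03, n=60, noise_floor=0.01):
    """Restoration-grade target: restricted S range, 1% errors."""
    s = np.linspace(0.002, s_max, n)
    i = sk.debye_intensity(model, s)
    sigma = noise_floor * i * (1.0 + s / s[-1])
    return sk.ScatteringProfile(s, i, sigma)
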