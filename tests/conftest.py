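import numpy as np
import pytest

from reprodyn import (
    ConventionalRIParams,
    GeneralizedRIParams,
    SpeciesParams,
    symmetric_community,
)

#: demographic baseline used throughout the phase-plane tests:
#: B0=20, s=0.5, D=2, H=0.1 gives carrying capacity (10 - 2) / 0.1 = 80
BASE = dict(B0=20.0, s=0.5, D=2.0, H=0.1)


@pytest.fixture
def base_species():
    return SpeciesParams(**BASE)


@pytest.fixture
def logistic_spec(base_species):
    """Uncoupled community: no interference in either direction."""
    return symmetric_community(base_species, GeneralizedRIParams(a=0.0), S=1.0)


@pytest.fixture
def generalized_spec(base_species):
    """Symmetric generalized community with moderate interference."""
    return symmetric_community(
        base_species, GeneralizedRIParams(a=1.0, b_ij=1.0, b_jj=1.0), S=1.0
    )


@pytest.fixture
def conventional_spec(base_species):
    return symmetric_community(base_species, ConventionalRIParams(i=1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_generalized_spec(rng: np.random.Generator):
    """A random viable symmetric generalized community for oracle sweeps."""
    s = rng.uniform(0.2, 0.8)
    B0 = rng.uniform(5.0, 50.0)
    D = rng.uniform(0.1, 0.5) * (1 - s) * B0
    H = rng.uniform(0.01, 0.5)
    sp = SpeciesParams(B0=B0, s=s, D=D, H=H)
    gi = GeneralizedRIParams(
        a=rng.uniform(0.05, 5.0), b_ij=rng.uniform(0.0, 3.0), b_jj=rng.uniform(0.05, 3.0)
    )
    return symmetric_community(sp, gi, S=rng.uniform(0.5, 5.0))


def random_conventional_spec(rng: np.random.Generator):
    s = rng.uniform(0.2, 0.8)
    B0 = rng.uniform(5.0, 50.0)
    D = rng.uniform(0.1, 0.5) * (1 - s) * B0
    H = rng.uniform(0.01, 0.5)
    sp = SpeciesParams(B0=B0, s=s, D=D, H=H)
    return symmetric_community(sp, ConventionalRIParams(i=rng.uniform(0.05, 5.0)))
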