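import numpy as np
import pytest

from coemit.simulate import FamilySpec, make_toy_hmms, simulate_families


@pytest.fixture(scope="session")
def toy_models():
    """Six random valid profiles of length 8 for I/O and scoring tests."""
    return make_toy_hmms(6, 8, seed=11)


@pytest.fixture(scope="session")
def tiny_models():
    """Short random profiles (L in 1..3) for brute-force path oracles."""
    out = []
    for L in (1, 2, 3):
        out.extend(make_toy_hmms(4, L, seed=100 + L))
    return out


@pytest.fixture(scope="session")
def family_data():
    """The default 4-family synthetic dataset with its truth table."""
    spec = FamilySpec(seed=7)
    records, truth = simulate_families(spec)
    return spec, records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_distance_matrix(rng, n):
    """A random symmetric zero-diagonal matrix in [0, 1]."""
    a = rng.random((n, n))
    d = np.triu(a, 1)
    d = d + d.T
    return d
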