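import numpy as np
import pytest

from stokespol import PolarimeterConfig, instrument_k


@pytest.fixture(scope="session")
def cfg():
    """Default polarimeter geometry (alpha 45 deg, beta 23 deg, A 2.405 rad)."""
    return PolarimeterConfig()


@pytest.fixture(scope="session")
def k_ideal(cfg):
    """Ground-truth K of the simulated instrument."""
    return instrument_k(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


def random_states(rng, n, partial=True):
    """Physical random Stokes states (fully or partially polarised)."""
    out = []
    for _ in range(n):
        vec = rng.normal(size=3)
        vec /= np.linalg.norm(vec)
        p = rng.uniform(0.2, 1.0) if partial else 1.0
        intensity = rng.uniform(0.5, 2.0)
        out.append(np.array([1.0, p * vec[0], p * vec[1], p * vec[2]]) * intensity)
    return out


def circular_angle_distance(a, b):
    """Distance between optic-axis angles defined modulo pi."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % np.pi
    return np.minimum(d, np.pi - d)
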