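import numpy as np
import pytest

from atherosim.geometry import build_annulus_domain, build_channel_domain
from atherosim.parameters import default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def unit_square():
    """Unit square meshed as a degenerate channel (periodic in x)."""
    return build_channel_domain(
        length=1.0, thickness=1.0, bump_amplitude=0.0, h=0.05, lumen_clearance=10.0
    )


@pytest.fixture(scope="session")
def annulus():
    return build_annulus_domain(0.9, 1.0, h=0.02)


@pytest.fixture(scope="session")
def channel():
    return build_channel_domain(h=1e-3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140312)


def random_positive_state(rng, n=1):
    """Random physically plausible nodal state for oracle comparisons."""
    scales = {
        "L": 1.9e-3, "H": 6e-4, "Lox": 1e-4, "r": 2.0,
        "M": 2e-5, "P": 5e-10, "T": 1e-3, "Ig": 1e-6,
        "S": 1e-6, "I12": 1e-8, "G": 1e-6, "Q": 1e-9,
        "Qr": 1e-9, "F": 1e-4,
    }
    out = {k: v * rng.random(n) for k, v in scales.items()}
    if n == 1:
        out = {k: float(v[0]) for k, v in out.items()}
    return out
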