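import numpy as np
import pytest

from bmcal import (LayerStack, Material, SI3N4, ALUMINUM,
                   reference_profile, default_profile)


@pytest.fixture
def ref_model():
    """Bundled reference scenario, with sample."""
    return reference_profile()


@pytest.fixture
def ref_beam_only():
    return reference_profile().without_sample()


@pytest.fixture
def box_model():
    """Same hardware with every geometric quantity derived from the boxes."""
    return default_profile()


@pytest.fixture
def ref_stack():
    return LayerStack(top=SI3N4, bottom=ALUMINUM, t1=1e-6, t2=0.5e-6)


@pytest.fixture
def symmetric_stack():
    """Identical layers (m = n = 1) apart from their expansion coefficients."""
    a = Material("a", 1000.0, 1000.0, 10.0, 30e-6, 100e9)
    b = Material("b", 1000.0, 1000.0, 10.0, 10e-6, 100e9)
    return LayerStack(top=b, bottom=a, t1=1e-6, t2=1e-6)


def make_stack(m, n, dalpha=20e-6, t2=0.5e-6):
    """Stack with thickness ratio m = t1/t2 and modulus ratio n = E1/E2."""
    top = Material("top", 1000.0, 1000.0, 10.0, 5e-6, 100e9 * n)
    bottom = Material("bottom", 1000.0, 1000.0, 10.0, 5e-6 + dalpha, 100e9)
    return LayerStack(top=top, bottom=bottom, t1=m * t2, t2=t2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
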