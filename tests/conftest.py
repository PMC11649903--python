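import numpy as np
import pytest

from e2chase.kinetics import KineticParams
from e2chase.synthetic import ToyGeometrySpec, gen_thioester_frame, toy_site


@pytest.fixture
def reference_params() -> KineticParams:
    """Rate constants typical of an intrinsically slow E2~Ub conjugate."""
    return KineticParams(k1=0.015, k2=3.8e-4, k3=0.002)


@pytest.fixture
def chase_times() -> np.ndarray:
    return np.linspace(0.0, 120.0, 12)


@pytest.fixture
def toy_frame():
    return gen_thioester_frame(ToyGeometrySpec(offset=3.0, angle=120.0, seed=2))


@pytest.fixture
def site():
    return toy_site()
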