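import numpy as np
import pytest

from ringmech.morphometry import SpecimenGeometry
from ringmech.traceio import TensileTrace, TestProtocol


@pytest.fixture
def protocol():
    return TestProtocol()


@pytest.fixture
def geometry():
    # 0.6 x 0.6 mm limb cross-section, a0 = pi * 0.09 ~ 0.2827 mm^2
    return SpecimenGeometry(widths=[0.6], heights=[0.6])


def make_trace(loads_mn, dt=0.05, speed=0.005, is_baseline=False):
    """Trace from a list of loads in mN on the protocol's uniform grid."""
    loads = np.asarray(loads_mn, dtype=float) / 1000.0
    t = np.arange(len(loads)) * dt
    return TensileTrace(
        time=t, extension=speed * t, load=loads, specimen_id="t", is_baseline=is_baseline
    )


@pytest.fixture
def trace_factory():
    return make_trace
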