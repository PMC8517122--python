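import numpy as np
import pytest

from dilv import SampleGrid, PressureParams, VolumeParams


@pytest.fixture
def demo_volume() -> VolumeParams:
    """Canonical pressure-controlled demo breath: sharp drive, unit tidal volume."""
    return VolumeParams(theta=0.3, a1=200.0, b1=0.7, phi1=0.0,
                        beta1=30.0, beta2=10.0, Av=1.0)


@pytest.fixture
def demo_pressure() -> PressureParams:
    """Demo pressure breath with both plateau peaks and the low-volume knee."""
    return PressureParams(theta=0.3, a2=200.0, b2=0.7, phi2=0.0,
                          a3=10.0, b3=0.9, phi3=-0.6, beta3=5.0, beta4=5.0,
                          beta5=1.001, beta6=1.1111,
                          Ap1=1.0, Ap2=0.5, Ap3=0.5, Ap4=0.0)


@pytest.fixture
def demo_grid() -> SampleGrid:
    """One period of the demo breath (theta = 0.3 /s) at 5 ms."""
    return SampleGrid(dt=0.005, n=667)


@pytest.fixture
def commensurate_grid() -> SampleGrid:
    """Two exact periods at theta = 0.25 /s: 800 samples/period at 5 ms."""
    return SampleGrid(dt=0.005, n=1600, burn_in_periods=5)


def relerr(est: float, true: float) -> float:
    return abs(est - true) / abs(true)
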