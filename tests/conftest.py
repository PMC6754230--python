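import numpy as np
import pytest

from kip2traffic.lattice import LatticeSpec, MotorKinetics, ReservoirSpec


@pytest.fixture(scope="session")
def clamped():
    return ReservoirSpec(closed=False)


@pytest.fixture(scope="session")
def small_kinetics():
    """Moderate-density parameter point used across small-lattice oracles."""
    return MotorKinetics(k_in=0.5, k_on=0.2, k_off=0.1, k_step=2.0, k_out=1.0, c_total=1.0)


@pytest.fixture(scope="session")
def wt_like_kinetics():
    """Wild-type-like kinetics: minus-end loading dominant, no lattice unbinding."""
    return MotorKinetics(
        k_in=0.01875, k_on=0.01875 / 500.0, k_off=0.0, k_step=13.125, k_out=4.0,
        c_total=35.0,
    )


@pytest.fixture(scope="session")
def lattice4():
    return LatticeSpec(4)
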