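import numpy as np
import pytest

from poreflux.density import FixedFrame, SoftCylinderRegion


@pytest.fixture(scope="session")
def region():
    return SoftCylinderRegion(R=4.0, dR=2.0, Z=6.0, dZ=2.0)


@pytest.fixture(scope="session")
def frame():
    return FixedFrame()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def ou_window_run():
    """Four long OU windows (k=1, D0=0.2, T=298) shared by the diffusion tests."""
    from poreflux.dynamics import integrate
    from poreflux.scenarios import make_scenario

    system = make_scenario(
        "ou_window",
        {"k": 1.0, "D0": 0.2, "dt": 0.01, "seed": 42, "centers": [0.0, 20.0, 40.0, 60.0]},
    )
    traj = integrate(system, 1_000_000, sample_stride=2)  # 10 ns, 0.02 ps sampling
    return system, traj
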