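import pytest

import afdm


@pytest.fixture(scope="session")
def geometry():
    return afdm.make_catheter_geometry()


@pytest.fixture(scope="session")
def rotor_acquisition():
    """Noisy rotor with 5 rotations at CL 170 ms."""
    return afdm.simulate_acquisition(
        "rotational", seed=1, n_beats=5, noise_sd_mv=0.05, duration_s=1.2
    )


@pytest.fixture(scope="session")
def planar_acquisition():
    return afdm.simulate_acquisition(
        "planar", seed=2, n_beats=8, noise_sd_mv=0.05, duration_s=1.6
    )


@pytest.fixture(scope="session")
def focal_acquisition():
    return afdm.simulate_acquisition(
        "focal", seed=3, n_beats=6, noise_sd_mv=0.05, duration_s=1.3
    )


@pytest.fixture(scope="session")
def atrium():
    return afdm.make_synthetic_atrium()


@pytest.fixture(scope="session")
def small_atrium():
    return afdm.make_synthetic_atrium(n_vertices=600)
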