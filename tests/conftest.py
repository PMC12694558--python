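import pytest

from kneegait import WalkSpec, generate_emg, generate_imu_walk, generate_pressure_walk


@pytest.fixture(scope="session")
def imu_walk():
    """Default synthetic walk: 16 steps of 1.13 m at 100 steps/min."""
    return generate_imu_walk(WalkSpec(seed=0))


@pytest.fixture(scope="session")
def imu_walk_clean():
    """Noise-free walk for analytic checks."""
    return generate_imu_walk(WalkSpec(accel_noise_sd=0.0, gyro_noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def pressure_walk():
    return generate_pressure_walk(WalkSpec(seed=0))


@pytest.fixture(scope="session")
def pressure_walk_clean():
    return generate_pressure_walk(WalkSpec(pressure_noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def emg_constant_centroid():
    """12 s of synthetic sEMG with a constant 100 Hz spectral centroid."""
    return generate_emg(12.0, 100.0, 100.0, seed=1)
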