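import numpy as np
import pytest

from ciliatip.synth import (
    OpticsParams,
    TrapSimParams,
    WaveformParams,
    generate_free_beating,
    generate_trapped_phase,
)


@pytest.fixture(scope="session")
def det_params():
    """Deterministic (no per-seed draws), noiseless default waveform."""
    return WaveformParams(freq_sd_hz=0.0, x_amplitude_sd_um=0.0, noise_sd_nm=0.0)


@pytest.fixture(scope="session")
def det_trajectory(det_params):
    return generate_free_beating(det_params, seed=1)


@pytest.fixture(scope="session")
def noisy_trajectory():
    p = WaveformParams(freq_sd_hz=0.0, x_amplitude_sd_um=0.0)  # default 10 nm noise
    return generate_free_beating(p, seed=2)


@pytest.fixture(scope="session")
def det_trap_params():
    return TrapSimParams(noise_sd_nm=0.0, residual_xy_amp_nm=0.0)


@pytest.fixture(scope="session")
def det_trapped(det_trap_params):
    return generate_trapped_phase(det_trap_params, seed=1)


@pytest.fixture(scope="session")
def optics():
    return OpticsParams()


@pytest.fixture(scope="session")
def quiet_optics():
    return OpticsParams(camera_noise_sd=0.0)
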