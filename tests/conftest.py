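"""Shared fixtures: small deterministic phantoms and simulated raw data."""

import numpy as np
import pytest

from aqueflow.phantom import (
    AcquisitionConfig,
    FlowWaveform,
    PhantomConfig,
    build_scene,
    simulate_coil_maps,
    simulate_kspace,
)


TINY_N = 64
TINY_FOV = 38.4  # keeps the paper's 0.6 mm pixel size


@pytest.fixture(scope="session")
def tiny_phantom_cfg():
    return PhantomConfig(matrix_size=TINY_N, fov_mm=TINY_FOV)


@pytest.fixture(scope="session")
def tiny_scene(tiny_phantom_cfg):
    return build_scene(tiny_phantom_cfg)


@pytest.fixture(scope="session")
def tiny_maps(tiny_phantom_cfg):
    return simulate_coil_maps(
        tiny_phantom_cfg.n_coils, tiny_phantom_cfg.matrix_size
    )


@pytest.fixture(scope="session")
def tiny_waveform():
    return FlowWaveform()


@pytest.fixture(scope="session")
def tiny_acq():
    return AcquisitionConfig(duration_s=6.0)


@pytest.fixture(scope="session")
def tiny_raw(tiny_scene, tiny_waveform, tiny_maps, tiny_acq):
    """6 s flow acquisition on the 64 x 64 phantom (285 spoke pairs)."""
    return simulate_kspace(tiny_scene, tiny_waveform, tiny_maps, tiny_acq)


@pytest.fixture(scope="session")
def tiny_static_raw(tiny_scene, tiny_maps, tiny_acq):
    """Same acquisition with the flow switched off (static scene)."""
    wf = FlowWaveform(resp_amplitude=0.0, card_amplitude=0.0)
    return simulate_kspace(tiny_scene, wf, tiny_maps, tiny_acq)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
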