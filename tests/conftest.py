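"""Shared fixtures: small deterministic synthetic volumes."""

import numpy as np
import pytest

from capiflow import octsim


@pytest.fixture(scope="session")
def small_protocol():
    return octsim.ScanProtocol(n_z=20, n_x=32, n_y=32)


@pytest.fixture(scope="session")
def standard_spec():
    """Default-amplitude network used across filter/velocimetry tests."""
    return octsim.CapillaryNetworkSpec(n_segments=30, seed=1)


@pytest.fixture(scope="session")
def standard_volume(small_protocol, standard_spec):
    truth = octsim.build_network(standard_spec, small_protocol)
    ens = octsim.synthesize_ensemble(truth, standard_spec, small_protocol)
    return truth, ens


@pytest.fixture(scope="session")
def noisefree_volume(small_protocol):
    spec = octsim.CapillaryNetworkSpec(n_segments=30, seed=1, noise_sigma=0.0)
    truth = octsim.build_network(spec, small_protocol)
    ens = octsim.synthesize_ensemble(truth, spec, small_protocol)
    return spec, truth, ens


def make_tone_block(freq_hz, n_repeats=50, interval=50e-6, n_voxels=5,
                    amplitude=1.0, noise=0.0, seed=0):
    """Complex tone repeat-series block with optional noise (oracle input)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_repeats) * interval
    phases = rng.uniform(0, 2 * np.pi, n_voxels)
    block = amplitude * np.exp(1j * (2 * np.pi * freq_hz * t[:, None]
                                     + phases[None, :]))
    if noise > 0:
        block = block + (noise / np.sqrt(2)) * (
            rng.standard_normal((n_repeats, n_voxels))
            + 1j * rng.standard_normal((n_repeats, n_voxels)))
    return block
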