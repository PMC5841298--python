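"""Eigen filter and Kasai estimator: exactness, adaptivity, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capiflow import edvel, octsim
from capiflow.calibration import velocity_to_frequency
from conftest import make_tone_block

T = 50e-6  # default repeat interval, s
NYQ = 1.0 / (2 * T)


# ---------------------------------------------------------------- covariance

def test_covariance_of_ones_is_rank_one():
    block = np.ones((50, 1), dtype=complex)
    cov = edvel.ensemble_covariance(block)
    assert cov.matrix.shape == (50, 50)
    assert np.allclose(cov.matrix, 1.0)
    eig = edvel.eigendecompose(cov, T)
    assert eig.eigenvalues[0] == pytest.approx(50.0)
    assert np.allclose(eig.eigenvalues[1:], 0.0, atol=1e-9)


def test_covariance_of_tone_has_phase_ramp_eigenvector():
    block = make_tone_block(1500.0, n_voxels=4)
    cov = edvel.ensemble_covariance(block)
    eig = edvel.eigendecompose(cov, T)
    assert eig.eigenvalues[0] == pytest.approx(50.0, rel=1e-9)
    assert eig.mean_frequencies[0] == pytest.approx(1500.0, rel=1e-9)


def test_covariance_noise_spectrum_flat():
    """i.i.d. noise at 1e4 voxels: eigenvalues near sigma^2 (MC oracle)."""
    rng = np.random.default_rng(0)
    sigma = 0.5
    block = (sigma / np.sqrt(2)) * (rng.standard_normal((50, 10_000))
                                    + 1j * rng.standard_normal((50, 10_000)))
    eig = edvel.eigendecompose(edvel.ensemble_covariance(block), T)
    assert np.all(np.abs(eig.eigenvalues - sigma ** 2) < 0.25 * sigma ** 2)


def test_covariance_rejects_short_series():
    with pytest.raises(ValueError):
        edvel.ensemble_covariance(np.ones((1, 5), dtype=complex))


def test_eigendecompose_rejects_non_hermitian():
    m = np.eye(4, dtype=complex)
    m[0, 1] = 1.0  # asymmetric
    with pytest.raises(ValueError):
        edvel.CovarianceMatrix(m, n_samples=1)


def test_eigenvalue_sum_equals_trace(standard_volume):
    """Energy conservation on real simulated blocks."""
    _, ens = standard_volume
    data = ens.data
    for x in (0, 7, 19):
        block = data[:, 0:5, x, x]
        cov = edvel.ensemble_covariance(block)
        eig = edvel.eigendecompose(cov, T)
        assert eig.eigenvalues.sum() == pytest.approx(cov.trace, rel=1e-10)
        recon = (eig.eigenvectors * eig.eigenvalues) @ eig.eigenvectors.conj().T
        assert np.allclose(recon, cov.matrix, atol=1e-8 * cov.trace)


# ------------------------------------------------------------ Kasai estimator

@pytest.mark.parametrize("freq", [1.0, 100.0, 1000.0, 2500.0, 6000.0,
                                  9000.0, 9999.0])
def test_kasai_exact_on_pure_tones(freq):
    t = np.arange(50) * T
    v = np.exp(2j * np.pi * freq * t)
    assert edvel.component_mean_frequency(v, T) == pytest.approx(freq,
                                                                 rel=1e-9)


@given(freq=st.floats(min_value=1.0, max_value=9999.0))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_kasai_exact_across_band(freq):
    """Exactness anywhere in (0, Nyquist), no premature wrapping."""
    t = np.arange(50) * T
    v = np.exp(2j * np.pi * freq * t)
    assert edvel.component_mean_frequency(v, T) == pytest.approx(freq,
                                                                 rel=1e-7)


def test_kasai_constant_vector_is_dc():
    assert edvel.component_mean_frequency(np.ones(50), T) == 0.0


def test_kasai_undefined_on_zero_autocorrelation():
    alternating = np.array([1.0, -1.0] * 25)  # sign flips: Nyquist tone
    assert edvel.component_mean_frequency(alternating, T) == pytest.approx(NYQ)
    gapped = np.array([1.0, 0.0] * 25)  # every lag-1 product vanishes
    assert np.isnan(edvel.component_mean_frequency(gapped, T))


def test_kasai_bias_decreases_with_snr():
    """RMS frequency error shrinks monotonically over 3 SNR levels."""
    f0 = 2000.0
    errors = []
    for noise in (2.0, 0.5, 0.05):
        errs = []
        for seed in range(40):
            block = make_tone_block(f0, n_voxels=20, noise=noise, seed=seed)
            eig = edvel.eigendecompose(edvel.ensemble_covariance(block), T)
            errs.append(abs(eig.mean_frequencies[0] - f0))
        errors.append(np.mean(errs))
    assert errors[0] > errors[1] > errors[2]


# -------------------------------------------------------------- clutter filter

def _two_component_eig(clutter_hz, blood_hz, clutter_amp=10.0, blood_amp=1.0):
    block = (make_tone_block(clutter_hz, n_voxels=6, amplitude=clutter_amp,
                             seed=1)
             + make_tone_block(blood_hz, n_voxels=6, amplitude=blood_amp,
                               seed=2))
    return edvel.eigendecompose(edvel.ensemble_covariance(block), T)


def test_static_only_block_yields_empty_retained():
    eig = edvel.eigendecompose(
        edvel.ensemble_covariance(make_tone_block(0.0, n_voxels=6,
                                                  amplitude=10.0)), T)
    res = edvel.adaptive_clutter_filter(eig)
    assert res.clutter_rank >= 1
    assert res.retained_indices.size == 0


def test_clutter_plus_blood_classification():
    eig = _two_component_eig(0.0, 2000.0)
    res = edvel.adaptive_clutter_filter(eig, static_threshold=100.0)
    assert res.clutter_rank == 1
    assert res.retained_indices.size == 1
    mf = eig.mean_frequencies[res.retained_indices[0]]
    assert mf == pytest.approx(2000.0, rel=0.02)


def test_drifting_clutter_still_classified():
    """50 Hz bulk drift stays under the 100 Hz threshold (adaptivity)."""
    eig = _two_component_eig(50.0, 2000.0)
    res = edvel.adaptive_clutter_filter(eig, static_threshold=100.0)
    assert res.clutter_rank == 1
    assert eig.mean_frequencies[0] == pytest.approx(50.0, rel=0.05)
    assert res.retained_indices.size == 1


def test_filter_ranks_by_amplitude():
    """Two dominant eigenvalues ordered by component amplitude^2."""
    eig = _two_component_eig(0.0, 3000.0, clutter_amp=10.0, blood_amp=2.0)
    # finite-voxel random-phase averaging leaves some cross-power
    assert eig.eigenvalues[0] / eig.eigenvalues[1] == pytest.approx(
        (10.0 / 2.0) ** 2, rel=0.15)


def test_brute_force_projection_equivalence():
    """<= 8 repeats: filter reconstruction matches explicit matrix math."""
    rng = np.random.default_rng(3)
    t = np.arange(8) * T
    block = (5.0 * np.exp(1j * rng.uniform(0, 2 * np.pi, (1, 4)))
             * np.ones((8, 1))
             + np.exp(2j * np.pi * 4000.0 * t)[:, None]
             * np.exp(1j * rng.uniform(0, 2 * np.pi, (1, 4))))
    eig = edvel.eigendecompose(edvel.ensemble_covariance(block), T)
    res = edvel.adaptive_clutter_filter(eig, power_floor=0.01,
                                        coherence_floor=0.3)
    assert res.retained_indices.size >= 1
    series = block[:, 2]
    fast = edvel.project_series(eig, series, res.retained_indices)
    # oracle: explicit sum of outer-product projectors
    proj = np.zeros((8, 8), dtype=complex)
    for i in res.retained_indices:
        v = eig.eigenvectors[:, i]
        proj += np.outer(v, v.conj())
    assert np.allclose(fast, proj @ series, atol=1e-10)


# ------------------------------------------------------------------- voxel MF

def test_pure_clutter_volume_all_invalid(small_protocol):
    spec = octsim.CapillaryNetworkSpec(n_segments=0, seed=2)
    truth = octsim.build_network(spec, small_protocol)
    ens = octsim.synthesize_ensemble(truth, spec, small_protocol)
    mfvol = edvel.voxel_mf(ens)
    assert mfvol.n_valid == 0


def test_noise_free_mf_recovery(noisefree_volume):
    """Noise-free: >= 99% of vessel voxels within 1% of true Doppler."""
    spec, truth, ens = noisefree_volume
    mfvol = edvel.voxel_mf(ens)
    f_true = velocity_to_frequency(truth.velocity, spec.calibration_slope)
    ok = mfvol.valid_mask & truth.vessel_mask
    assert ok.sum() >= 0.99 * truth.vessel_mask.sum()
    rel = np.abs(mfvol.mf[ok] - f_true[ok]) / f_true[ok]
    assert (rel < 0.01).mean() >= 0.99


def test_static_leakage_below_one_percent(standard_volume):
    """Filter specificity on the standard noisy fixture."""
    truth, ens = standard_volume
    mfvol = edvel.voxel_mf(ens)
    static = ~truth.vessel_mask
    leak = (mfvol.valid_mask & static).sum() / static.sum()
    assert leak <= 0.01


def test_mf_within_nyquist(standard_volume, small_protocol):
    _, ens = standard_volume
    mfvol = edvel.voxel_mf(ens)
    vals = mfvol.mf[mfvol.valid_mask]
    assert np.all((vals >= 0) & (vals <= small_protocol.nyquist_hz))


def test_mf_to_velocity_roundtrip(standard_volume, standard_spec):
    """Simulate at v0, estimate MF, map back: generator's inverse map."""
    truth, ens = standard_volume
    mfvol = edvel.voxel_mf(ens)
    vel = edvel.mf_to_velocity(mfvol, standard_spec.calibration_slope)
    ok = vel.valid_mask & truth.vessel_mask
    rel = np.abs(vel.velocity[ok] - truth.velocity[ok]) / truth.velocity[ok]
    assert np.median(rel) < 0.02
    assert (rel < 0.1).mean() > 0.95


def test_mf_to_velocity_linearity(standard_volume):
    _, ens = standard_volume
    mfvol = edvel.voxel_mf(ens)
    v1 = edvel.mf_to_velocity(mfvol, 1e-3)
    v2 = edvel.mf_to_velocity(mfvol, 2e-3)
    assert np.allclose(v2.velocity, 2 * v1.velocity, equal_nan=True)
    assert np.all(v1.velocity[v1.valid_mask] >= 0)
    with pytest.raises(ValueError):
        edvel.mf_to_velocity(mfvol, 0.0)


def test_second_clutter_component_removed(small_protocol):
    """Adaptive rank: a second tissue component is also filtered out."""
    spec = octsim.CapillaryNetworkSpec(
        n_segments=10, seed=6, second_clutter_amplitude=3.0,
        second_clutter_drift_hz=30.0)
    truth = octsim.build_network(spec, small_protocol)
    ens = octsim.synthesize_ensemble(truth, spec, small_protocol)
    mfvol = edvel.voxel_mf(ens)
    static = ~truth.vessel_mask
    assert (mfvol.valid_mask & static).sum() / static.sum() <= 0.01
    ok = mfvol.valid_mask & truth.vessel_mask
    assert ok.sum() >= 0.95 * truth.vessel_mask.sum()


def test_full_protocol_yields_over_20000_mf_signals():
    """Default acquisition protocol (200 x 100 positions, 50 repeats) on a
    dense capillary bed: at least 20,000 valid MF estimates recovered."""
    proto = octsim.ScanProtocol()
    spec = octsim.CapillaryNetworkSpec(n_segments=950, seed=0)
    truth = octsim.build_network(spec, proto)
    assert truth.vessel_mask.sum() >= 20_000
    ens = octsim.synthesize_ensemble(truth, spec, proto)
    mfvol = edvel.voxel_mf(ens)
    assert mfvol.n_valid >= 20_000
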