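"""Transit-time conversion, gamma fitting, MTT/CTTH, histogram shifts."""

import numpy as np
import pytest
from scipy import stats

from capiflow import transit

# Table-style operating point: alpha = (MTT/CTTH)^2, beta = CTTH^2/MTT
ALPHA, BETA = 3.127, 0.1318


def gamma_sample(n, alpha=ALPHA, beta=BETA, seed=0):
    return np.random.default_rng(seed).gamma(alpha, beta, size=n)


# ------------------------------------------------------------------ tau = L/v

def test_unit_conversion():
    s = transit.velocity_to_transit(np.array([1.0]), 400.0)
    assert s.tau[0] == pytest.approx(0.4)


def test_conversion_at_mean_transit_velocity():
    # hand-calculated: 0.4 mm / 1.037 mm/s
    s = transit.velocity_to_transit(np.array([1.037]), 400.0)
    assert s.tau[0] == pytest.approx(0.4 / 1.037)
    assert s.tau[0] == pytest.approx(0.3857, abs=2e-4)


def test_default_path_length():
    assert transit.DEFAULT_PATH_LENGTH_UM == 400.0
    s = transit.velocity_to_transit(np.array([2.0]))
    assert s.tau[0] == pytest.approx(0.2)


def test_invalid_velocities_excluded():
    v = np.array([1.0, 0.0, -0.5, np.nan, 2.0])
    s = transit.velocity_to_transit(v)
    assert s.tau.size == 2
    with pytest.raises(ValueError):
        transit.velocity_to_transit(np.zeros(5))


def test_enface_mask_restricts_sample():
    v = np.ones((4, 3, 3))
    mask2d = np.zeros((3, 3), dtype=bool)
    mask2d[1, 1] = True
    s = transit.velocity_to_transit(v, capillary_mask=mask2d)
    assert s.tau.size == 4  # one column through depth


# ----------------------------------------------------------------- histograms

def test_histogram_normalization():
    d = transit.make_distribution(gamma_sample(5000))
    widths = np.diff(d.bin_edges)
    assert np.sum(d.density * widths) == pytest.approx(1.0)
    assert np.all(d.density >= 0)


def test_identical_values_single_bin():
    d = transit.make_distribution(np.full(500, 0.4))
    assert (d.density > 0).sum() == 1
    w = np.diff(d.bin_edges)[d.density > 0][0]
    assert d.density.max() == pytest.approx(1.0 / w)


def test_histogram_mean_matches_sample():
    x = gamma_sample(100_000, alpha=4.0, beta=0.1, seed=3)
    d = transit.make_distribution(x)
    c = d.bin_centers
    mean = np.sum(c * d.density * np.diff(d.bin_edges))
    assert mean == pytest.approx(0.4, rel=0.01)


def test_small_sample_rejected():
    with pytest.raises(ValueError, match="at least"):
        transit.make_distribution(gamma_sample(50))


# ------------------------------------------------------------------ gamma fit

def test_fit_recovers_exact_density():
    """No sampling noise: alpha, beta recovered to 4 significant digits."""
    edges = np.linspace(1e-4, 1.5, 121)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = stats.gamma.pdf(centers, ALPHA, scale=BETA)
    density /= np.sum(density * np.diff(edges))
    dist = transit.TransitTimeDistribution(edges, density, n=10**6)
    fit = transit.fit_gamma(dist)
    assert fit.alpha == pytest.approx(ALPHA, rel=5e-4)
    assert fit.beta == pytest.approx(BETA, rel=5e-4)
    assert fit.r_squared > 0.9999


def test_fit_identities():
    """MTT = alpha*beta, CTTH = sqrt(alpha)*beta, MTT/CTTH = sqrt(alpha)."""
    fit = transit.fit_gamma(transit.make_distribution(gamma_sample(20_000)))
    assert fit.mtt == pytest.approx(fit.alpha * fit.beta, rel=1e-12)
    assert fit.ctth == pytest.approx(np.sqrt(fit.alpha) * fit.beta, rel=1e-12)
    assert fit.mtt / fit.ctth == pytest.approx(np.sqrt(fit.alpha), rel=1e-12)


def test_fit_matches_mle_cross_check():
    x = gamma_sample(50_000, seed=9)
    fit = transit.fit_gamma(transit.make_distribution(x))
    a_mle, b_mle = transit.fit_gamma_mle(x)
    assert fit.alpha == pytest.approx(a_mle, rel=0.05)
    assert fit.beta == pytest.approx(b_mle, rel=0.05)


def test_parameter_recovery_median_error():
    """100 seeded replicates at n = 2e4: median relative MTT error <= 2%."""
    errs = []
    for seed in range(100):
        fit = transit.fit_gamma(
            transit.make_distribution(gamma_sample(20_000, seed=seed)))
        errs.append(abs(fit.mtt - ALPHA * BETA) / (ALPHA * BETA))
    assert np.median(errs) <= 0.02


def test_fit_stable_under_binwidth_perturbation():
    """MTT within +-2% across +-50% bin-width changes."""
    x = gamma_sample(20_000, seed=4)
    base = transit.make_distribution(x)
    n_bins = base.density.size
    mtts = []
    for bins in (n_bins, int(n_bins / 1.5), int(n_bins * 1.5)):
        fit = transit.fit_gamma(transit.make_distribution(x, bins=bins))
        mtts.append(fit.mtt)
    assert max(mtts) / min(mtts) - 1 < 0.04  # pairwise within +-2%


def test_r_squared_improves_with_sample_size():
    """Median R^2 increases monotonically over n in {1e3, 1e4, 1e5}."""
    medians = []
    for n in (1_000, 10_000, 100_000):
        r2 = [transit.fit_gamma(
                  transit.make_distribution(gamma_sample(n, seed=s))
              ).r_squared for s in range(5)]
        medians.append(np.median(r2))
    assert medians[0] < medians[1] < medians[2]


def test_jensen_bound():
    """MTT (mean of L/v) >= L / mean(v) for any velocity sample."""
    rng = np.random.default_rng(11)
    for _ in range(5):
        v = rng.lognormal(0.0, 0.6, size=2000)
        s = transit.velocity_to_transit(v, 400.0)
        assert s.tau.mean() >= 0.4 / v.mean() - 1e-12


# -------------------------------------------------------------- differentiation

def test_identical_histograms_no_switch():
    d = transit.make_distribution(gamma_sample(5000))
    diff = transit.differentiate_histograms(d, d)
    assert np.allclose(diff.difference, 0.0)
    assert diff.sign_switch_tau is None
    assert diff.all_switches.size == 0


def test_stimulation_shift_produces_sign_switch():
    """Stim gamma with 10% lower mean: positive at short tau, negative at
    long tau, dominant switch near the analytic density crossing."""
    rest = gamma_sample(200_000, seed=1)
    stim = gamma_sample(200_000, alpha=ALPHA, beta=BETA * 0.9, seed=2)
    edges = np.linspace(0, 1.2, 61)
    d_rest = transit.make_distribution(rest, bins=edges)
    d_stim = transit.make_distribution(stim, bins=edges)
    diff = transit.differentiate_histograms(d_rest, d_stim)
    centers = 0.5 * (diff.bin_edges[:-1] + diff.bin_edges[1:])
    # analytic oracle: crossing of the two gamma densities
    tau = np.linspace(1e-4, 1.2, 20_000)
    delta = (stats.gamma.pdf(tau, ALPHA, scale=0.9 * BETA)
             - stats.gamma.pdf(tau, ALPHA, scale=BETA))
    crossing = tau[np.argmax(np.signbit(delta[np.argmax(delta):])
                             ) + np.argmax(delta)]
    early = diff.difference[centers < 0.6 * crossing]
    late = diff.difference[(centers > 1.5 * crossing) & (centers < 0.9)]
    assert early.mean() > 0
    assert late.mean() < 0
    assert diff.sign_switch_tau == pytest.approx(crossing, abs=0.06)
    # both densities normalized: difference integrates to ~0
    assert abs(np.sum(diff.difference * np.diff(diff.bin_edges))) < 1e-6


def test_differentiation_rebins_mismatched_edges():
    rest = transit.make_distribution(gamma_sample(20_000, seed=5))
    stim = transit.make_distribution(gamma_sample(20_000, beta=0.9 * BETA,
                                                  seed=6))
    diff = transit.differentiate_histograms(rest, stim)
    assert abs(np.sum(diff.difference * np.diff(diff.bin_edges))) < 1e-6
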