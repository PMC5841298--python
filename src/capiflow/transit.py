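"""Transit-time distributions, gamma-law fitting, MTT/CTTH, histogram shifts.

Per-capillary RBC speeds v are converted to transit times τ = L / v
under a uniform capillary path length L (default 400 µm).  The τ sample
is binned into a normalized histogram and fitted, by nonlinear least
squares, with the two-parameter gamma density

    h(τ; α, β) = τ^(α-1) e^(-τ/β) / (β^α Γ(α)),

whose mean αβ is the mean transit time (MTT) and whose standard
deviation √α·β is the capillary transit-time heterogeneity (CTTH).  An
explicit amplitude degree of freedom A·h(τ) is carried in the curve fit
so the α, β estimates do not depend on the counts-vs-density convention;
A ≈ 1 for a well-normalized histogram.  Rest-vs-stimulation histogram
differentiation (stim − rest density per bin) locates the transit-time
value where the flow redistribution changes sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .edvel import VelocityVolume

__all__ = [
    "TransitTimeSample",
    "TransitTimeDistribution",
    "GammaFit",
    "HistogramDifferentiation",
    "DEFAULT_PATH_LENGTH_UM",
    "velocity_to_transit",
    "make_distribution",
    "fit_gamma",
    "fit_gamma_mle",
    "differentiate_histograms",
]

logger = logging.getLogger(__name__)

#: Uniform capillary path length used to convert speed to transit time, µm.
DEFAULT_PATH_LENGTH_UM: float = 400.0

_MIN_SAMPLES = 100


@dataclass
class TransitTimeSample:
    """Per-capillary transit times τ = L/v with their source velocities."""

    tau: np.ndarray  # s
    velocity: np.ndarray  # mm/s
    path_length_um: float
    n_excluded: int = 0  # zero/invalid velocities dropped

    def __post_init__(self) -> None:
        if np.any(self.tau <= 0):
            raise ValueError("transit times must be positive")


@dataclass
class TransitTimeDistribution:
    """Normalized transit-time histogram: Σ density·bin_width = 1."""

    bin_edges: np.ndarray  # s
    density: np.ndarray
    n: int

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges)
        if np.any(self.density < 0) or np.any(widths <= 0):
            raise ValueError("invalid histogram")
        total = float(np.sum(self.density * widths))
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"density must integrate to 1, got {total}")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class GammaFit:
    """Gamma-law fit: MTT = αβ, CTTH = √α·β, so MTT/CTTH ≡ √α."""

    alpha: float
    beta: float  # s
    amplitude: float
    r_squared: float
    n: int
    at_bound: bool = False

    @property
    def mtt(self) -> float:
        return self.alpha * self.beta

    @property
    def ctth(self) -> float:
        return float(np.sqrt(self.alpha)) * self.beta

    def pdf(self, tau: np.ndarray) -> np.ndarray:
        return self.amplitude * stats.gamma.pdf(tau, self.alpha, scale=self.beta)


@dataclass
class HistogramDifferentiation:
    """Per-bin density difference (stimulation − rest) on shared edges."""

    bin_edges: np.ndarray
    difference: np.ndarray
    sign_switch_tau: Optional[float]  # dominant crossing, s
    all_switches: np.ndarray  # every crossing edge, s


def velocity_to_transit(
    vel: Union[VelocityVolume, np.ndarray],
    path_length_um: float = DEFAULT_PATH_LENGTH_UM,
    capillary_mask: Optional[np.ndarray] = None,
) -> TransitTimeSample:
    """τ = L / v per valid capillary voxel; invalid/zero speeds dropped.

    ``capillary_mask`` (2-D en-face or full 3-D) restricts the sample to
    capillary voxels, e.g. after large-vessel removal.
    """
    if path_length_um <= 0:
        raise ValueError("path length must be positive")
    if isinstance(vel, VelocityVolume):
        v = vel.velocity
        valid = vel.valid_mask.copy()
    else:
        v = np.asarray(vel, dtype=float)
        valid = np.isfinite(v)
    if capillary_mask is not None:
        m = np.asarray(capillary_mask, dtype=bool)
        if m.ndim == v.ndim - 1:  # en-face mask broadcast over depth
            m = np.broadcast_to(m, v.shape)
        valid = valid & m
    sel = valid & np.isfinite(v) & (v > 0)
    n_excluded = int(valid.sum() - sel.sum())
    vv = v[sel]
    if vv.size == 0:
        raise ValueError("no valid positive velocities to convert")
    if n_excluded:
        logger.info("velocity_to_transit: excluded %d zero/invalid voxels",
                    n_excluded)
    tau = (path_length_um / 1000.0) / vv
    return TransitTimeSample(tau, vv, path_length_um, n_excluded)


def make_distribution(
    taus: Union[TransitTimeSample, np.ndarray],
    bins: Union[str, int, Sequence[float]] = "fd",
    upper_quantile: float = 0.995,
) -> TransitTimeDistribution:
    """Normalized histogram of transit times.

    Default binning is Freedman–Diaconis width on the range
    [0, ``upper_quantile`` percentile]; the extreme tail is excluded so
    a handful of near-zero velocities cannot stretch the support.
    """
    t = taus.tau if isinstance(taus, TransitTimeSample) else np.asarray(taus)
    t = t[np.isfinite(t)]
    if t.size < _MIN_SAMPLES:
        raise ValueError(
            f"need at least {_MIN_SAMPLES} transit times (got {t.size}); "
            "enlarge the sample")
    hi = float(np.quantile(t, upper_quantile))
    kept = t[t <= hi]
    if np.ptp(kept) == 0:  # degenerate: all identical values
        w = max(abs(kept[0]) * 1e-3, 1e-9)
        edges = np.array([kept[0] - w / 2, kept[0] + w / 2])
    elif isinstance(bins, str):
        edges = np.histogram_bin_edges(kept, bins=bins, range=(0.0, hi))
    else:
        edges = np.histogram_bin_edges(kept, bins=bins, range=(0.0, hi)) \
            if np.isscalar(bins) else np.asarray(bins, dtype=float)
    density, edges = np.histogram(kept, bins=edges, density=True)
    return TransitTimeDistribution(edges, density, n=kept.size)


def _gamma_model(tau, alpha, beta, amplitude):
    return amplitude * stats.gamma.pdf(tau, alpha, scale=beta)


def fit_gamma(dist: TransitTimeDistribution,
              bounds: tuple[float, float] = (1e-3, 1e3)) -> GammaFit:
    """Least-squares fit of A·h(τ; α, β) to the histogram points.

    Initialized by method of moments on the histogram (α₀ = mean²/var,
    β₀ = var/mean, A₀ = 1); parameters bounded in (1e-3, 1e3).  R² is
    the coefficient of determination of the fitted curve against the
    histogram density at bin centers.
    """
    tau = dist.bin_centers
    y = dist.density
    widths = np.diff(dist.bin_edges)
    mean = float(np.sum(tau * y * widths))
    var = float(np.sum((tau - mean) ** 2 * y * widths))
    var = max(var, 1e-12)
    a0 = float(np.clip(mean ** 2 / var, *bounds))
    b0 = float(np.clip(var / mean, *bounds)) if mean > 0 else 1.0
    lo, hi = bounds
    try:
        popt, _ = optimize.curve_fit(
            _gamma_model, tau, y, p0=[a0, b0, 1.0],
            bounds=([lo, lo, 0.1], [hi, hi, 10.0]), maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"gamma fit did not converge (initializer alpha={a0:.4g}, "
            f"beta={b0:.4g})") from err
    alpha, beta, amp = map(float, popt)
    at_bound = bool(np.isclose(alpha, lo) or np.isclose(alpha, hi)
                    or np.isclose(beta, lo) or np.isclose(beta, hi))
    if at_bound:
        logger.warning("gamma fit pinned at parameter bound "
                       "(alpha=%.4g, beta=%.4g)", alpha, beta)
    yhat = _gamma_model(tau, alpha, beta, amp)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GammaFit(alpha, beta, amp, max(min(r2, 1.0), 0.0), dist.n, at_bound)


def fit_gamma_mle(taus: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood gamma fit on raw samples (cross-check oracle)."""
    a, _, b = stats.gamma.fit(np.asarray(taus), floc=0)
    return float(a), float(b)


def _rebin(dist: TransitTimeDistribution,
           edges: np.ndarray) -> np.ndarray:
    """Piecewise-constant rebin of a density onto new edges."""
    cum = np.concatenate([[0.0], np.cumsum(dist.density
                                           * np.diff(dist.bin_edges))])
    cdf = np.interp(edges, dist.bin_edges, cum, left=0.0, right=cum[-1])
    mass = np.diff(cdf)
    widths = np.diff(edges)
    total = mass.sum()
    if total <= 0:
        raise ValueError("rebinning produced an empty distribution")
    return mass / total / widths


def differentiate_histograms(
    rest: TransitTimeDistribution,
    stim: TransitTimeDistribution,
) -> HistogramDifferentiation:
    """Per-bin stim − rest density difference and its sign switch(es).

    Distributions with differing edges are rebinned onto the finer
    common grid first.  The dominant switch is the edge where the
    cumulative difference mass is extremal (the boundary between the
    gained-short-τ and lost-long-τ regions); all sign changes are
    listed.
    """
    if np.array_equal(rest.bin_edges, stim.bin_edges):
        edges = rest.bin_edges
        d_rest, d_stim = rest.density, stim.density
    else:
        lo = min(rest.bin_edges[0], stim.bin_edges[0])
        hi = max(rest.bin_edges[-1], stim.bin_edges[-1])
        n_bins = max(rest.density.size, stim.density.size)
        edges = np.linspace(lo, hi, n_bins + 1)
        d_rest = _rebin(rest, edges)
        d_stim = _rebin(stim, edges)
    diff = d_stim - d_rest
    widths = np.diff(edges)

    sign = np.sign(diff)
    nz = np.flatnonzero(sign)
    switches = []
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] != sign[b]:
            switches.append(edges[b])  # leading edge of the flipping bin
    switches = np.asarray(switches)
    if switches.size:
        cum = np.cumsum(diff * widths)
        k = int(np.argmax(np.abs(cum)))
        dominant = float(edges[k + 1])
    else:
        dominant = None
    return HistogramDifferentiation(edges, diff, dominant, switches)
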