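"""Synthetic OCT M-scan ensemble simulator with known ground truth.

Emulates the acquisition used for eigen-decomposition capillary
velocimetry: at every transverse position a burst of repeated A-lines
(an M-scan) samples the complex backscattered field.  The per-voxel
repeat series is modelled as the sum of three components:

* static-tissue **clutter** — a high-amplitude complex tone with a
  (near-zero) residual bulk-motion frequency and near-unity temporal
  correlation;
* **blood** — inside vessel voxels, a tone at the Doppler frequency
  mapped from the ground-truth RBC speed through the shared linear
  calibration, multiplied by a Gaussian decorrelation envelope that
  gives the moving-scatterer signal a finite spectral bandwidth;
* circularly-symmetric complex Gaussian **noise** (the shot-noise-limited
  OCT approximation).

Vessels are straight cylindrical segments with random position and
orientation; each segment carries one RBC speed drawn as ``v = L / τ``
with τ a gamma(α, β) transit time, so the ensemble of segments realises
a known transit-time law for recovery experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .calibration import DEFAULT_CALIBRATION_SLOPE, velocity_to_frequency

__all__ = [
    "ScanProtocol",
    "CapillaryNetworkSpec",
    "GroundTruth",
    "MScanEnsemble",
    "NyquistError",
    "sample_transit_times",
    "build_network",
    "synthesize_ensemble",
    "synthesize_omag_volume",
]


class NyquistError(ValueError):
    """A drawn velocity maps beyond the Nyquist-limited Doppler range."""


@dataclass(frozen=True)
class ScanProtocol:
    """M-scan acquisition geometry and timing.

    Defaults reproduce the velocimetry protocol: 50 repeated A-lines per
    position at a 20 kHz rate (50 µs interval), 200 × 100 transverse
    positions at 7.5 µm/pixel, 1340 nm center wavelength.
    """

    n_repeats: int = 50
    repeat_interval: float = 50e-6  # s between successive A-lines
    n_z: int = 40
    n_x: int = 200
    n_y: int = 100
    pixel_size_xy: float = 7.5  # µm / pixel, transverse
    pixel_size_z: float = 7.5  # µm / pixel, axial
    center_wavelength: float = 1340.0  # nm

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        if self.repeat_interval <= 0:
            raise ValueError("repeat_interval must be positive")
        for name in ("n_z", "n_x", "n_y"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def nyquist_hz(self) -> float:
        """Maximum unambiguous Doppler frequency, 1/(2·repeat_interval)."""
        return 1.0 / (2.0 * self.repeat_interval)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_z, self.n_x, self.n_y)


@dataclass(frozen=True)
class CapillaryNetworkSpec:
    """Parameters of the synthetic capillary bed and its signal model.

    The transit-time law is gamma(alpha, beta); defaults are the shape
    and scale implied by a resting capillary bed with mean transit time
    0.412 s and transit-time heterogeneity 0.233 s
    (alpha = (MTT/CTTH)^2, beta = CTTH^2/MTT).
    """

    n_segments: int = 120
    diameter_range: tuple[float, float] = (5.0, 10.0)  # µm, capillaries
    large_vessel_fraction: float = 0.15  # fraction of wide (surface) vessels
    large_diameter_range: tuple[float, float] = (18.0, 30.0)  # µm, > cutoff
    depth_range: tuple[float, float] = (0.0, 300.0)  # µm below surface
    alpha: float = 3.127  # gamma shape of the transit-time law
    beta: float = 0.1318  # gamma scale, seconds
    path_length_um: float = 400.0  # uniform capillary path length L
    segment_length_range: tuple[float, float] = (40.0, 120.0)  # µm
    clutter_amplitude: float = 10.0
    blood_amplitude: float = 1.0
    noise_sigma: float = 0.1
    clutter_drift_hz: float = 0.0  # residual bulk-motion frequency
    second_clutter_amplitude: float = 0.0  # optional second tissue component
    second_clutter_drift_hz: float = 30.0
    decorrelation_time: float = 5e-3  # s; Gaussian blood-envelope scale
    frame_interval: float = 2.5e-3  # s between repeated B-scan frames
    calibration_slope: float = DEFAULT_CALIBRATION_SLOPE  # (mm/s)/Hz
    strict_nyquist: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("gamma parameters alpha, beta must be positive")
        if self.path_length_um <= 0:
            raise ValueError("path_length_um must be positive")
        for name in ("clutter_amplitude", "blood_amplitude", "noise_sigma",
                     "second_clutter_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_segments < 0:
            raise ValueError("n_segments must be >= 0")
        lo, hi = self.diameter_range
        if not (0 < lo <= hi):
            raise ValueError("diameter_range must be positive and ordered")
        if not 0 <= self.large_vessel_fraction <= 1:
            raise ValueError("large_vessel_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Per-voxel truth emitted by the network builder.

    velocity is the RBC speed in mm/s (0 outside vessels), diameter the
    local vessel diameter in µm, vessel_mask the vessel support.
    ``segments`` records one row per placed segment (tau_s,
    velocity_mm_s, diameter_um, n_voxels) for distribution-level checks.
    """

    velocity: np.ndarray  # (n_z, n_x, n_y), mm/s
    diameter: np.ndarray  # (n_z, n_x, n_y), µm
    vessel_mask: np.ndarray  # (n_z, n_x, n_y), bool
    segments: pd.DataFrame
    n_truncated_draws: int = 0

    def __post_init__(self) -> None:
        if not np.array_equal(self.velocity > 0, self.vessel_mask):
            raise ValueError("velocity must be positive exactly on vessel_mask")
        if np.any(self.diameter[~self.vessel_mask] != 0):
            raise ValueError("diameter must be zero outside vessel_mask")


@dataclass
class MScanEnsemble:
    """4-D complex OCT signal, repeat × z × x × y, plus acquisition metadata."""

    data: np.ndarray
    protocol: ScanProtocol
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("ensemble data must be 4-D (repeat, z, x, y)")
        if self.data.shape[1:] != self.protocol.shape:
            raise ValueError("ensemble spatial shape inconsistent with protocol")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ensemble contains non-finite values")


def _max_velocity_mm_s(spec: CapillaryNetworkSpec, protocol: ScanProtocol) -> float:
    return protocol.nyquist_hz * spec.calibration_slope


def sample_transit_times(
    alpha: float,
    beta: float,
    n: int,
    rng: np.random.Generator,
    tau_min: Optional[float] = None,
    strict: bool = False,
    max_rounds: int = 200,
) -> tuple[np.ndarray, int]:
    """Draw n transit times from gamma(alpha, beta), optionally truncated.

    When ``tau_min`` is given, draws below it (which would imply a
    velocity beyond the Nyquist-mapped maximum) are rejected and
    redrawn; the count of rejected draws is returned.  With
    ``strict=True`` the first offending draw raises instead.
    """
    taus = rng.gamma(alpha, beta, size=n)
    n_truncated = 0
    if tau_min is not None:
        if strict:
            bad = np.flatnonzero(taus < tau_min)
            if bad.size:
                i = int(bad[0])
                raise NyquistError(
                    f"transit-time draw {i} (tau={taus[i]:.4g} s) implies a "
                    f"velocity beyond the Nyquist-mapped maximum "
                    f"(tau_min={tau_min:.4g} s)"
                )
        for _ in range(max_rounds):
            bad = taus < tau_min
            n_bad = int(bad.sum())
            if n_bad == 0:
                break
            n_truncated += n_bad
            taus[bad] = rng.gamma(alpha, beta, size=n_bad)
        else:
            raise RuntimeError("truncated gamma resampling did not converge")
    return taus, n_truncated


def build_network(
    spec: CapillaryNetworkSpec,
    protocol: ScanProtocol,
    max_retries: int = 50,
    taus_override: Optional[np.ndarray] = None,
) -> GroundTruth:
    """Voxelise a random network of straight capillary segments.

    Each segment carries one speed ``v = L / tau`` with tau drawn from
    the gamma transit-time law, and a diameter drawn uniformly from
    ``diameter_range``.  Deterministic under ``spec.seed``; the
    geometry stream is independent of the transit-time stream, so two
    specs sharing a seed produce the same network layout even when
    their (α, β) differ.  ``taus_override`` substitutes per-segment
    transit times (clipped to the Nyquist-safe floor), which lets a
    paired condition reuse a network with re-mapped flows.
    """
    ss = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(ss[0])  # transit-time stream
    rng_geom = np.random.default_rng(ss[1])  # geometry stream
    shape = protocol.shape
    velocity = np.zeros(shape, dtype=np.float64)
    diameter = np.zeros(shape, dtype=np.float64)

    if spec.n_segments == 0:
        return GroundTruth(velocity, diameter, velocity > 0,
                           pd.DataFrame(columns=["tau_s", "velocity_mm_s",
                                                 "diameter_um", "n_voxels"]))

    v_max = _max_velocity_mm_s(spec, protocol)
    L_mm = spec.path_length_um / 1000.0
    tau_min = L_mm / v_max
    if taus_override is not None:
        taus = np.maximum(np.asarray(taus_override, dtype=float), tau_min)
        if taus.size != spec.n_segments:
            raise ValueError("taus_override length must equal n_segments")
        n_trunc = int((np.asarray(taus_override) < tau_min).sum())
    else:
        taus, n_trunc = sample_transit_times(
            spec.alpha, spec.beta, spec.n_segments, rng,
            tau_min=tau_min, strict=spec.strict_nyquist)
    velocities = L_mm / taus
    # capillary/large-vessel mixture: mostly small-bore capillaries with
    # a sparse population of wide surface vessels above the cutoff
    diameters = rng_geom.uniform(*spec.diameter_range, size=spec.n_segments)
    is_large = rng_geom.random(spec.n_segments) < spec.large_vessel_fraction
    if is_large.any():
        diameters[is_large] = rng_geom.uniform(*spec.large_diameter_range,
                                               size=int(is_large.sum()))

    extent = np.array([protocol.n_z * protocol.pixel_size_z,
                       protocol.n_x * protocol.pixel_size_xy,
                       protocol.n_y * protocol.pixel_size_xy])
    z_lo = max(spec.depth_range[0], 0.0)
    z_hi = min(spec.depth_range[1], extent[0])
    if z_hi <= z_lo:
        raise ValueError("depth_range does not intersect the volume")
    pix = np.array([protocol.pixel_size_z, protocol.pixel_size_xy,
                    protocol.pixel_size_xy])

    rows = []
    for i in range(spec.n_segments):
        placed = False
        for _ in range(max_retries):
            p0 = np.array([rng_geom.uniform(z_lo, z_hi),
                           rng_geom.uniform(0, extent[1]),
                           rng_geom.uniform(0, extent[2])])
            # random orientation, biased transverse like cortical capillary mats
            d = rng_geom.normal(size=3)
            d[0] *= 0.3
            norm = np.linalg.norm(d)
            if norm == 0:
                continue
            d /= norm
            length = rng_geom.uniform(*spec.segment_length_range)
            p1 = p0 + d * length
            n_vox = _rasterize_segment(velocity, diameter, p0, p1,
                                       diameters[i], velocities[i], pix)
            if n_vox > 0:
                rows.append((taus[i], velocities[i], diameters[i], n_vox))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place segment {i} after {max_retries} retries; "
                "grid too small for the requested network")

    segments = pd.DataFrame(rows, columns=["tau_s", "velocity_mm_s",
                                           "diameter_um", "n_voxels"])
    return GroundTruth(velocity, diameter, velocity > 0, segments,
                       n_truncated_draws=n_trunc)


def _rasterize_segment(velocity, diameter, p0, p1, diam_um, v_mm_s, pix) -> int:
    """Paint a cylinder of given diameter around segment p0→p1 (µm coords).

    Returns the number of voxels painted.  Later segments overwrite
    earlier ones at intersections (last-wins; intersections are rare and
    irrelevant to the velocity marginals).
    """
    radius = max(diam_um / 2.0, 0.51 * float(np.min(pix)))  # ≥ one-voxel line
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    idx_lo = np.maximum(np.floor(lo / pix).astype(int), 0)
    idx_hi = np.minimum(np.ceil(hi / pix).astype(int) + 1,
                        np.array(velocity.shape))
    if np.any(idx_hi <= idx_lo):
        return 0
    grids = np.meshgrid(*[(np.arange(idx_lo[a], idx_hi[a]) + 0.5) * pix[a]
                          for a in range(3)], indexing="ij")
    pts = np.stack(grids, axis=-1)  # (..., 3) voxel centers, µm
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    rel = pts - p0
    t = np.clip((rel @ seg) / seg_len2, 0.0, 1.0) if seg_len2 > 0 else 0.0
    nearest = p0 + t[..., None] * seg
    dist = np.linalg.norm(pts - nearest, axis=-1)
    inside = dist <= radius
    if not np.any(inside):
        return 0
    sl = tuple(slice(idx_lo[a], idx_hi[a]) for a in range(3))
    velocity[sl][inside] = v_mm_s
    diameter[sl][inside] = diam_um
    return int(inside.sum())


def _signal_model(
    truth: GroundTruth,
    spec: CapillaryNetworkSpec,
    protocol: ScanProtocol,
    n_repeats: int,
    interval: float,
    rng: np.random.Generator,
    blood_frame_decorrelation: bool,
) -> np.ndarray:
    """Shared clutter + blood + noise model on an arbitrary repeat axis."""
    shape = protocol.shape
    t = (np.arange(n_repeats, dtype=np.float64) * interval)[:, None]

    # clutter: per-voxel static speckle phase, common slow drift
    phi_c = rng.uniform(0, 2 * np.pi, size=shape).reshape(-1)
    rot = np.exp(2j * np.pi * spec.clutter_drift_hz * t).astype(np.complex64)
    data = spec.clutter_amplitude * (
        rot * np.exp(1j * phi_c)[None, :].astype(np.complex64))
    if spec.second_clutter_amplitude > 0:
        phi_c2 = rng.uniform(0, 2 * np.pi, size=shape).reshape(-1)
        rot2 = np.exp(2j * np.pi * spec.second_clutter_drift_hz * t
                      ).astype(np.complex64)
        data += spec.second_clutter_amplitude * (
            rot2 * np.exp(1j * phi_c2)[None, :].astype(np.complex64))

    mask = truth.vessel_mask.reshape(-1)
    if spec.blood_amplitude > 0 and mask.any():
        v = truth.velocity.reshape(-1)[mask]
        f = velocity_to_frequency(v, spec.calibration_slope)
        if not blood_frame_decorrelation:
            # aliasing matters only on the fast (M-scan) repeat axis;
            # the slow B-scan frame axis relies on decorrelation contrast
            nyq = 1.0 / (2.0 * interval)
            if np.any(np.abs(f) > nyq):
                raise NyquistError("ground-truth velocity maps beyond Nyquist")
        phi_b = rng.uniform(0, 2 * np.pi, size=f.size)
        carrier = np.exp(1j * (2 * np.pi * f[None, :] * t + phi_b[None, :]))
        if blood_frame_decorrelation:
            # inter-frame speckle decorrelation: AR(1) complex modulation
            rho = float(np.exp(-0.5 * (interval / spec.decorrelation_time) ** 2))
            g = (rng.standard_normal((n_repeats, f.size))
                 + 1j * rng.standard_normal((n_repeats, f.size))) / np.sqrt(2)
            b = np.empty_like(g)
            b[0] = g[0]
            for k in range(1, n_repeats):
                b[k] = rho * b[k - 1] + np.sqrt(1 - rho ** 2) * g[k]
            blood = spec.blood_amplitude * b * carrier
        else:
            env = np.exp(-0.5 * (t / spec.decorrelation_time) ** 2)
            blood = spec.blood_amplitude * env * carrier
        data[:, mask] += blood.astype(np.complex64)

    if spec.noise_sigma > 0:
        noise = rng.standard_normal((n_repeats,) + (data.shape[1],), dtype=np.float32) \
            + 1j * rng.standard_normal((n_repeats,) + (data.shape[1],), dtype=np.float32)
        data += (spec.noise_sigma / np.sqrt(2)) * noise.astype(np.complex64)

    return data.reshape((n_repeats,) + shape)


def synthesize_ensemble(
    truth: GroundTruth,
    spec: CapillaryNetworkSpec,
    protocol: ScanProtocol,
) -> MScanEnsemble:
    """Generate the M-scan ensemble for a ground-truth network.

    Each voxel's repeat series is clutter + (inside vessels) an
    enveloped Doppler tone at ``f = v / calibration_slope`` + complex
    noise.  Bit-deterministic under ``spec.seed``.
    """
    if truth.velocity.shape != protocol.shape:
        raise ValueError("truth shape inconsistent with protocol")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    data = _signal_model(truth, spec, protocol, protocol.n_repeats,
                         protocol.repeat_interval, rng,
                         blood_frame_decorrelation=False)
    prov = {"seed": spec.seed, "kind": "mscan",
            "spec": dataclasses.asdict(spec)}
    return MScanEnsemble(data, protocol, prov)


def synthesize_omag_volume(
    truth: GroundTruth,
    spec: CapillaryNetworkSpec,
    protocol: ScanProtocol,
    n_brepeats: int = 8,
) -> MScanEnsemble:
    """Generate a repeated-B-scan volume for the angiogram path.

    Same signal classes on a slower repeat axis (default 8 frames at
    ``spec.frame_interval``); blood decorrelates between frames (AR(1)
    speckle), static tissue repeats identically up to noise, which is
    what gives the frame-difference angiogram its contrast.
    """
    if n_brepeats < 2:
        raise ValueError("n_brepeats must be >= 2")
    if truth.velocity.shape != protocol.shape:
        raise ValueError("truth shape inconsistent with protocol")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    data = _signal_model(truth, spec, protocol, n_brepeats,
                         spec.frame_interval, rng,
                         blood_frame_decorrelation=True)
    prov = {"seed": spec.seed, "kind": "omag", "n_brepeats": n_brepeats,
            "spec": dataclasses.asdict(spec)}
    return MScanEnsemble(data, protocol, prov)
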