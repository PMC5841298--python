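"""End-to-end synthetic experiment driver.

Emulates a two-region (activated HLS1 vs control CTRL), two-condition
(rest vs stimulation) study across ``n_animals`` animals: for each
animal × region × condition a capillary volume is simulated at
per-animal transit-time parameters, the full analysis chain
(eigen-velocimetry → angiogram segmentation → gamma transit-time fit)
is run, and the fitted per-animal MTV/MTT/CTTH feed the between-region
statistics.

Per-animal variability is injected on (MTT, CTTH) — resting values are
drawn around the group means, and each animal's stimulation values
apply the group rest→stim ratio with optional per-animal noise — then
mapped to gamma parameters via α = (MTT/CTTH)², β = CTTH²/MTT.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import angio, edvel, groupstats, transit
from .octsim import (CapillaryNetworkSpec, ScanProtocol, build_network,
                     synthesize_ensemble, synthesize_omag_volume)

__all__ = ["RegionParams", "ExperimentConfig", "ExperimentResult",
           "run_experiment", "analyze_volume"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionParams:
    """Group-level transit-time parameters (s) for one region."""

    rest_mtt: float
    rest_ctth: float
    stim_mtt: float
    stim_ctth: float


#: Group parameters of a resting/activated somatosensory study (seconds).
DEFAULT_REGIONS = {
    "HLS1": RegionParams(0.412, 0.233, 0.367, 0.218),
    "CTRL": RegionParams(0.387, 0.229, 0.382, 0.227),
}


@dataclass(frozen=True)
class ExperimentConfig:
    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    n_animals: int = 12
    #: between-animal std of resting MTT / CTTH (s)
    between_mtt_std: float = 0.05
    between_ctth_std: float = 0.025
    #: per-animal std of the rest→stim relative change (fraction, e.g. 0.022)
    delta_mtt_std: float = 0.022
    delta_ctth_std: float = 0.014
    protocol: ScanProtocol = field(default_factory=lambda: ScanProtocol(
        n_z=32, n_x=96, n_y=96))
    network: CapillaryNetworkSpec = field(
        default_factory=lambda: CapillaryNetworkSpec(
            n_segments=200, depth_range=(0.0, 240.0)))
    filter_params: edvel.FilterParams = field(default_factory=edvel.FilterParams)
    path_length_um: float = transit.DEFAULT_PATH_LENGTH_UM
    segment_vessels: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")


@dataclass
class ExperimentResult:
    records: list  # AnimalRecord
    changes: list  # RelativeChange
    comparisons: dict  # parameter -> RegionComparison
    fits: dict  # (animal, region, condition) -> GammaFit
    summary: pd.DataFrame
    failures: list  # (animal, region, condition, reason)
    provenance: dict

    @property
    def complete(self) -> bool:
        return not self.failures


def _gamma_from_moments(mtt: float, ctth: float) -> tuple[float, float]:
    return (mtt / ctth) ** 2, ctth ** 2 / mtt


def analyze_volume(
    spec: CapillaryNetworkSpec,
    protocol: ScanProtocol,
    filter_params: edvel.FilterParams,
    path_length_um: float,
    segment_vessels: bool = True,
    truth=None,
    capillary_mask=None,
):
    """Simulate one volume and run the full single-volume analysis.

    Returns (mtv, GammaFit, n_valid, capillary_mask).  Angiogram
    segmentation runs on a repeated-B-scan volume of the same network
    and removes en-face vessels wider than 15 µm before transit
    statistics.  A prebuilt ``truth`` lets paired conditions share a
    network; a supplied ``capillary_mask`` (e.g. from the resting scan
    of the same region — the vasculature does not change between
    conditions) skips re-segmentation.
    """
    if truth is None:
        truth = build_network(spec, protocol)
    ens = synthesize_ensemble(truth, spec, protocol)
    mfvol = edvel.voxel_mf(ens, filter_params)
    velvol = edvel.mf_to_velocity(mfvol, spec.calibration_slope)

    if capillary_mask is None and segment_vessels:
        omag = synthesize_omag_volume(truth, spec, protocol)
        ang = angio.omag_angiogram(omag)
        enface = angio.enface_project(ang.flow_signal, protocol.pixel_size_z,
                                      mode="max",
                                      slab_um=(0.0, protocol.n_z
                                               * protocol.pixel_size_z))
        seg = angio.segment_capillaries(enface.values,
                                        pixel_size_um=protocol.pixel_size_xy)
        if seg.capillary_mask.any():
            capillary_mask = seg.capillary_mask

    taus = transit.velocity_to_transit(velvol, path_length_um,
                                       capillary_mask=capillary_mask)
    dist = transit.make_distribution(taus)
    fit = transit.fit_gamma(dist)
    mtv = float(taus.velocity.mean())
    return mtv, fit, mfvol.n_valid, capillary_mask


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the multi-animal synthetic experiment; deterministic per seed."""
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    records, fits, failures = [], {}, []
    child = iter(ss.spawn(config.n_animals * len(config.regions) * 2 + 8))
    for a in range(config.n_animals):
        animal = f"m{a:02d}"
        for region, rp in config.regions.items():
            rest_mtt = max(rng.normal(rp.rest_mtt, config.between_mtt_std),
                           0.05)
            rest_ctth = max(rng.normal(rp.rest_ctth, config.between_ctth_std),
                            0.03)
            ratio_mtt = rp.stim_mtt / rp.rest_mtt \
                * (1.0 + rng.normal(0.0, config.delta_mtt_std))
            ratio_ctth = rp.stim_ctth / rp.rest_ctth \
                * (1.0 + rng.normal(0.0, config.delta_ctth_std))
            cond_params = {"rest": (rest_mtt, rest_ctth),
                           "stimulation": (rest_mtt * ratio_mtt,
                                           rest_ctth * ratio_ctth)}
            # paired scans: both conditions image the same capillary
            # network; stimulation transit times are the rest draws
            # quantile-mapped from the rest gamma law to the
            # stimulation law (flow redistributes in the same vessels)
            seed_i = int(next(child).generate_state(1)[0] % (2 ** 31))
            a_r, b_r = _gamma_from_moments(*cond_params["rest"])
            truth_rest = None
            shared_mask = None
            for cond, (mtt, ctth) in cond_params.items():
                alpha, beta = _gamma_from_moments(mtt, ctth)
                spec = replace(config.network, alpha=alpha, beta=beta,
                               seed=seed_i)
                try:
                    if cond == "rest":
                        truth = build_network(spec, config.protocol)
                        truth_rest = truth
                    else:
                        if truth_rest is None:
                            raise RuntimeError("rest network unavailable")
                        u = stats.gamma.cdf(
                            truth_rest.segments["tau_s"].to_numpy(),
                            a_r, scale=b_r)
                        tau_stim = stats.gamma.ppf(np.clip(u, 1e-12, 1 - 1e-12),
                                                   alpha, scale=beta)
                        truth = build_network(spec, config.protocol,
                                              taus_override=tau_stim)
                    mtv, fit, _, shared_mask = analyze_volume(
                        spec, config.protocol, config.filter_params,
                        config.path_length_um, config.segment_vessels,
                        truth=truth, capillary_mask=shared_mask)
                except Exception as err:  # stage failure: skip animal cell
                    logger.warning("animal %s %s %s failed: %s",
                                   animal, region, cond, err)
                    failures.append((animal, region, cond, str(err)))
                    continue
                fits[(animal, region, cond)] = fit
                records.append(groupstats.AnimalRecord(
                    animal, region, cond, mtv, fit.mtt, fit.ctth))

    df = pd.DataFrame([vars(r) for r in records],
                      columns=["animal_id", "region", "condition",
                               "mtv", "mtt", "ctth"])
    changes = []
    for (animal, region), sub in df.groupby(["animal_id", "region"]):
        by_cond = {r.condition: r for r in sub.itertuples()}
        if set(by_cond) != set(groupstats.CONDITIONS):
            failures.append((animal, region, "pairing",
                             "incomplete rest/stimulation pair"))
            continue
        rest = next(r for r in records if r.animal_id == animal
                    and r.region == region and r.condition == "rest")
        stim = next(r for r in records if r.animal_id == animal
                    and r.region == region and r.condition == "stimulation")
        changes.append(groupstats.relative_change(rest, stim))

    comparisons = {}
    for p in groupstats.PARAMETERS:
        try:
            comparisons[p] = groupstats.compare_regions(changes, p)
        except ValueError as err:  # incomplete design after failures
            failures.append(("-", "-", f"compare:{p}", str(err)))
    try:
        summary = groupstats.summarize_table(records)
    except ValueError as err:
        failures.append(("-", "-", "summary", str(err)))
        summary = pd.DataFrame()
    provenance = {
        "seed": config.seed,
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items()
               if k not in ("regions", "protocol", "network",
                            "filter_params")},
            "regions": {k: dataclasses.asdict(v)
                        for k, v in config.regions.items()},
            "protocol": dataclasses.asdict(config.protocol),
            "network": dataclasses.asdict(config.network),
            "filter_params": dataclasses.asdict(config.filter_params),
        },
    }
    return ExperimentResult(records, changes, comparisons, fits, summary,
                            failures, provenance)
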