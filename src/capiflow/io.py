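"""HDF5 container for ensembles, ground truth and derived results.

Layout: dataset "ensemble" (complex64, repeat × z × x × y); group
"truth" with "velocity" (mm/s), "diameter" (µm), "mask"; group
"protocol" carrying all acquisition attributes; derived volumes under
"results/..." with their parameters as attributes.  Units are recorded
as dataset attributes throughout.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .edvel import MFVolume, VelocityVolume
from .octsim import CapillaryNetworkSpec, GroundTruth, MScanEnsemble, ScanProtocol

__all__ = ["save_volume", "load_ensemble", "load_truth",
           "save_mf_results", "load_mf_results"]


def save_volume(path, ensemble: MScanEnsemble,
                truth: Optional[GroundTruth] = None,
                spec: Optional[CapillaryNetworkSpec] = None) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("ensemble",
                             data=ensemble.data.astype(np.complex64))
        d.attrs["axes"] = "repeat,z,x,y"
        g = f.create_group("protocol")
        for k, v in dataclasses.asdict(ensemble.protocol).items():
            g.attrs[k] = v
        g.attrs["units"] = json.dumps({
            "repeat_interval": "s", "pixel_size_xy": "um/pixel",
            "pixel_size_z": "um/pixel", "center_wavelength": "nm"})
        f.attrs["provenance"] = json.dumps(ensemble.provenance, default=str)
        if truth is not None:
            t = f.create_group("truth")
            t.create_dataset("velocity", data=truth.velocity).attrs["units"] = "mm/s"
            t.create_dataset("diameter", data=truth.diameter).attrs["units"] = "um"
            t.create_dataset("mask", data=truth.vessel_mask)
            t.attrs["n_truncated_draws"] = truth.n_truncated_draws
            t.create_dataset("segments",
                             data=truth.segments.to_numpy(dtype=float))
            t.attrs["segment_columns"] = list(truth.segments.columns)
        if spec is not None:
            s = f.create_group("network_spec")
            for k, v in dataclasses.asdict(spec).items():
                s.attrs[k] = v


def _protocol_from_attrs(attrs) -> ScanProtocol:
    fields = {f.name for f in dataclasses.fields(ScanProtocol)}
    kw = {k: attrs[k] for k in attrs if k in fields}
    for k in ("n_repeats", "n_z", "n_x", "n_y"):
        kw[k] = int(kw[k])
    return ScanProtocol(**kw)


def load_ensemble(path) -> MScanEnsemble:
    with h5py.File(path, "r") as f:
        protocol = _protocol_from_attrs(f["protocol"].attrs)
        prov = json.loads(f.attrs.get("provenance", "{}"))
        return MScanEnsemble(f["ensemble"][...], protocol, prov)


def load_truth(path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        t = f["truth"]
        segments = pd.DataFrame(t["segments"][...],
                                columns=list(t.attrs["segment_columns"]))
        return GroundTruth(t["velocity"][...], t["diameter"][...],
                           t["mask"][...].astype(bool), segments,
                           int(t.attrs.get("n_truncated_draws", 0)))


def save_mf_results(path, mfvol: MFVolume,
                    velvol: Optional[VelocityVolume] = None,
                    angiogram: Optional[np.ndarray] = None,
                    diameter: Optional[np.ndarray] = None,
                    capillary_mask: Optional[np.ndarray] = None,
                    params: Optional[dict] = None) -> None:
    """Append derived volumes under "results/" in an existing container."""
    with h5py.File(path, "a") as f:
        if "results" in f:
            del f["results"]
        g = f.create_group("results")
        d = g.create_dataset("mf", data=mfvol.mf)
        d.attrs["units"] = "Hz"
        g.create_dataset("valid_mask", data=mfvol.valid_mask)
        if velvol is not None:
            d = g.create_dataset("velocity", data=velvol.velocity)
            d.attrs["units"] = "mm/s"
            d.attrs["calibration_slope_mm_s_per_hz"] = velvol.calibration_slope
        if angiogram is not None:
            g.create_dataset("angiogram", data=angiogram)
        if diameter is not None:
            g.create_dataset("diameter", data=diameter).attrs["units"] = "um"
        if capillary_mask is not None:
            g.create_dataset("capillary_mask", data=capillary_mask)
        if params:
            g.attrs["params"] = json.dumps(params, default=str)


def load_mf_results(path) -> MFVolume:
    with h5py.File(path, "r") as f:
        protocol = _protocol_from_attrs(f["protocol"].attrs)
        g = f["results"]
        return MFVolume(g["mf"][...], g["valid_mask"][...].astype(bool),
                        protocol)
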