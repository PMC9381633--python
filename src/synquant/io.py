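"""Reading and writing the package's file formats.

Multi-channel fields go to TIFF with a JSON sidecar carrying pixel size,
channel names and provenance; traces and rasters to CSV (HDF5 optional
for traces); vesicle annotations to JSON with nm coordinates; tables to
CSV.  YAML is used for analysis configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .em import VesicleAnnotation
from .imaging import ROI, FieldOfView
from .mea import SpikeTrain
from .minis import CurrentTrace


# --- fields ---------------------------------------------------------------

def write_field(fov: FieldOfView, path: str | Path) -> None:
    """Write a field as multi-channel TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    names = list(fov.channels)
    stack = np.stack([fov.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack",
                     metadata={"axes": "CYX"})
    sidecar = {
        "pixel_size_um": fov.pixel_size,
        "channels": names,
        "metadata": {k: v for k, v in fov.metadata.items()
                     if isinstance(v, (str, int, float, bool))},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_field(path: str | Path) -> FieldOfView:
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    channels = {name: stack[i].astype(float)
                for i, name in enumerate(sidecar["channels"])}
    return FieldOfView(channels, sidecar["pixel_size_um"],
                       sidecar.get("metadata", {}))


# --- traces ---------------------------------------------------------------

def write_trace_csv(trace: CurrentTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times_s,
                  "current_pA": trace.samples_pa}).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> CurrentTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace needs at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return CurrentTrace(df["current_pA"].to_numpy(), fs)


def write_trace_hdf5(trace: CurrentTrace, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("current_pA", data=trace.samples_pa)
        f.attrs["sampling_rate_hz"] = trace.sampling_rate


def read_trace_hdf5(path: str | Path) -> CurrentTrace:
    import h5py

    with h5py.File(path, "r") as f:
        return CurrentTrace(f["current_pA"][:], float(f.attrs["sampling_rate_hz"]))


# --- rasters --------------------------------------------------------------

def write_raster_csv(trains: list[SpikeTrain], path: str | Path) -> None:
    """Long-format CSV: one row per spike (channel, time_s)."""
    rows = [(tr.channel_id, t) for tr in trains for t in tr.spike_times]
    pd.DataFrame(rows, columns=["channel", "time_s"]).to_csv(path, index=False)


def read_raster_csv(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [
        SpikeTrain(str(ch), np.sort(sub["time_s"].to_numpy()))
        for ch, sub in df.groupby("channel", sort=True)
    ]


# --- EM annotations -------------------------------------------------------

def write_annotation(ann: VesicleAnnotation, path: str | Path) -> None:
    payload = {
        "synapse_id": ann.synapse_id,
        "terminal_polygon_nm": ann.terminal_polygon.tolist(),
        "membrane_polyline_nm": ann.membrane_polyline.tolist(),
        "vesicle_centers_nm": ann.centers.tolist(),
        "vesicle_diameters_nm": ann.diameters.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_annotation(path: str | Path) -> VesicleAnnotation:
    d = json.loads(Path(path).read_text())
    for key in ("synapse_id", "terminal_polygon_nm", "membrane_polyline_nm",
                "vesicle_centers_nm", "vesicle_diameters_nm"):
        if key not in d:
            raise ValueError(f"annotation file missing {key!r}")
    return VesicleAnnotation(
        d["synapse_id"],
        np.asarray(d["terminal_polygon_nm"], dtype=float),
        np.asarray(d["membrane_polyline_nm"], dtype=float),
        np.asarray(d["vesicle_centers_nm"], dtype=float).reshape(-1, 2),
        np.asarray(d["vesicle_diameters_nm"], dtype=float),
    )


# --- ROIs and config ------------------------------------------------------

def read_rois(path: str | Path) -> list[ROI]:
    """JSON list of polygons, each an [[x_um, y_um], ...] vertex list."""
    data = json.loads(Path(path).read_text())
    return [ROI(np.asarray(poly, dtype=float)) for poly in data]


def write_rois(rois: list[ROI], path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.vertices_um.tolist() for r in rois]))


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}
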