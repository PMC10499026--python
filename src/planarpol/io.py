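"""Shared file I/O: TIFF/PNG rasters and the package's CSV dialects."""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .follicles import Correction, CorrectionSet, FollicleRecord
from .tracks import Track


def read_raster(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    from imageio.v3 import imread
    return imread(path)


def write_raster(path, array: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(array)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        from imageio.v3 import imwrite
        if arr.dtype in (np.float64, np.float32):
            arr = np.clip(arr * 255.0, 0, 255).astype(np.uint8)
        imwrite(path, arr)


def follicles_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": r.id, "x_px": r.x, "y_px": r.y,
        "angle_deg": r.angle if r.polarized else np.nan,
        "polarized": r.polarized, "source": r.source,
    } for r in records])


def write_follicles(path, records) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    follicles_to_frame(records).to_csv(path, index=False)


def read_follicles(path) -> list[FollicleRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        pol = bool(row["polarized"])
        ang = float(row["angle_deg"]) if pol else float("nan")
        out.append(FollicleRecord(int(row["id"]), float(row["x_px"]),
                                  float(row["y_px"]), ang, pol,
                                  str(row.get("source", "detected"))))
    return out


def read_corrections(path) -> CorrectionSet:
    """Corrections CSV: columns id, action, value.

    value is the angle for set_angle, or 'x;y[;angle]' for add."""
    df = pd.read_csv(path)
    corrections = []
    for _, row in df.iterrows():
        action = str(row["action"])
        fid = None if (isinstance(row["id"], float) and math.isnan(row["id"])) \
            else int(row["id"])
        payload = {}
        val = row.get("value")
        if action == "set_angle":
            payload["angle"] = float(val)
        elif action == "add":
            parts = str(val).split(";")
            payload["x"], payload["y"] = float(parts[0]), float(parts[1])
            if len(parts) > 2:
                payload["angle"] = float(parts[2])
        corrections.append(Correction(fid, action, payload))
    return CorrectionSet(corrections)


def write_tracks(path, tracks) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in tracks:
        for t, x, y in zip(tr.t, tr.x, tr.y):
            rows.append({"track_id": tr.track_id, "t": t, "x_px": x, "y_px": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks(path) -> list[Track]:
    df = pd.read_csv(path)
    out = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t")
        out.append(Track(int(tid), g["t"].to_numpy(float),
                         g["x_px"].to_numpy(float), g["y_px"].to_numpy(float)))
    return out


def write_flow_grid(path, grid) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    X, Y = np.meshgrid(grid.xs, grid.ys)
    pd.DataFrame({
        "x": X.ravel(), "y": Y.ravel(),
        "axial_deg": grid.axial_angle.ravel(),
        "vector_deg": grid.vector_angle.ravel(),
        "coherence": grid.coherence.ravel(),
    }).to_csv(path, index=False)


def write_nematics(path, nematics, nmap=None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([{
        "cell_id": n.cell_id, "x": n.x, "y": n.y,
        "angle_deg": n.angle, "magnitude": n.magnitude,
    } for n in nematics])
    if nmap is not None:
        extra = pd.DataFrame({
            "cell_id": nmap.cell_ids,
            "avg_angle_deg": nmap.avg_angle,
            "avg_magnitude": nmap.avg_magnitude,
        })
        if nmap.saturation is not None:
            extra["saturation"] = nmap.saturation
        df = df.merge(extra, on="cell_id", how="left")
    df.to_csv(path, index=False)
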