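"""Follicle position/orientation detection from two-channel placode images.

An embryonic hair placode carries two marker populations: one labels the
anteriorly displaced cell cluster (P-Cadherin-like channel A) and one the
posteriorly displaced cluster (Sox9-like channel B).  The follicle's
orientation vector is read out from the relative displacement of the two
blob centroids; concentric blobs mean the follicle is unpolarized (grows
straight down).  Detection is semi-automated: residual errors are fixed
by file-based corrections rather than interactive editing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram
from skimage.filters import gaussian, threshold_otsu

from .conventions import angle_from_vector, orientation_color, wrap_angle

logger = logging.getLogger(__name__)

#: sentinel stored in `angle` for unpolarized records
UNDEFINED_ANGLE = float("nan")


@dataclass
class FollicleRecord:
    """One hair follicle: position, 360°-valued orientation, polarity flag.

    `angle` is in degrees in (-180, 180], 0° = anterior, ±180° = posterior,
    and is finite iff `polarized`.
    """

    id: int
    x: float
    y: float
    angle: float = UNDEFINED_ANGLE
    polarized: bool = True
    source: str = "detected"  # detected | corrected | ground_truth

    def __post_init__(self):
        if self.polarized:
            if not math.isfinite(self.angle):
                raise ValueError(f"polarized follicle {self.id} needs a finite angle")
            self.angle = float(wrap_angle(self.angle))
        else:
            self.angle = UNDEFINED_ANGLE


@dataclass
class Correction:
    """One correction action against a follicle table."""

    follicle_id: int | None
    action: str  # set_angle | set_unpolarized | delete | add
    payload: dict = field(default_factory=dict)


@dataclass
class CorrectionSet:
    corrections: list[Correction] = field(default_factory=list)


@dataclass
class DetectionParams:
    smoothing_sigma: float = 2.0
    threshold_method: str = "otsu"  # relative: intensity-scale invariant
    min_area_px: int = 9
    max_pair_distance_px: float = 30.0
    unpolarized_offset_px: float | None = None  # default 0.25 x median blob radius

    def __post_init__(self):
        if self.smoothing_sigma <= 0 or self.min_area_px <= 0 \
                or self.max_pair_distance_px <= 0:
            raise ValueError("detection parameters must be positive")


def _blob_centroids(channel: np.ndarray, params: DetectionParams):
    """Smooth -> threshold -> connected components -> area filter.

    Returns (centroids (n,2) as (x, y), radii) where radius is the
    equivalent-circle radius sqrt(area/pi)."""
    sm = gaussian(channel.astype(float), sigma=params.smoothing_sigma,
                  preserve_range=True)
    if np.ptp(sm) == 0:
        return np.empty((0, 2)), np.empty(0)
    thr = threshold_otsu(sm)
    lab, n = ndimage.label(sm > thr)
    if n == 0:
        return np.empty((0, 2)), np.empty(0)
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(lab), lab, idx)
    keep = areas >= params.min_area_px
    if not keep.any():
        return np.empty((0, 2)), np.empty(0)
    coms = ndimage.center_of_mass(sm, lab, idx[keep])  # (row, col)
    cents = np.array([(c, r) for r, c in coms], dtype=float)
    radii = np.sqrt(areas[keep] / np.pi)
    return cents, radii


def _greedy_pair(cent_a, cent_b, cutoff):
    """Greedy matching on ascending centroid distance; each blob used once.

    Returns list of (ia, ib, distance)."""
    if len(cent_a) == 0 or len(cent_b) == 0:
        return []
    d = np.linalg.norm(cent_a[:, None, :] - cent_b[None, :, :], axis=-1)
    order = np.argsort(d, axis=None, kind="stable")
    used_a, used_b, pairs = set(), set(), []
    for flat in order:
        ia, ib = np.unravel_index(flat, d.shape)
        if d[ia, ib] > cutoff:
            break
        if ia in used_a or ib in used_b:
            continue
        used_a.add(int(ia))
        used_b.add(int(ib))
        pairs.append((int(ia), int(ib), float(d[ia, ib])))
    return pairs


def detect_follicles(channel_a: np.ndarray, channel_b: np.ndarray,
                     params: DetectionParams | None = None,
                     return_residuals: bool = False):
    """Detect follicles from the anterior-marker (A) and posterior-marker (B)
    channels.

    Position is the midpoint of the paired blob centroids; the orientation
    vector points from the B centroid to the A centroid (A is anterior in
    wild type).  Pairs closer than ``unpolarized_offset_px`` are flagged
    unpolarized.  Unmatched blobs are reported as residuals, not dropped
    silently.
    """
    params = params or DetectionParams()
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel rasters must share a shape")

    cent_a, rad_a = _blob_centroids(a, params)
    cent_b, rad_b = _blob_centroids(b, params)
    if len(cent_a) == 0 or len(cent_b) == 0:
        logger.info("empty channel: %d A blobs, %d B blobs", len(cent_a), len(cent_b))

    offset = params.unpolarized_offset_px
    if offset is None:
        radii = np.concatenate([rad_a, rad_b])
        offset = 0.25 * float(np.median(radii)) if len(radii) else 0.0

    pairs = _greedy_pair(cent_a, cent_b, params.max_pair_distance_px)
    records = []
    for i, (ia, ib, dist) in enumerate(pairs):
        ax, ay = cent_a[ia]
        bx, by = cent_b[ib]
        x, y = (ax + bx) / 2.0, (ay + by) / 2.0
        if dist < offset:
            records.append(FollicleRecord(i, x, y, polarized=False))
        else:
            ang = float(angle_from_vector(ax - bx, ay - by))
            records.append(FollicleRecord(i, x, y, angle=ang, polarized=True))

    if return_residuals:
        matched_a = {ia for ia, _, _ in pairs}
        matched_b = {ib for _, ib, _ in pairs}
        residuals = {
            "unmatched_a": [tuple(cent_a[i]) for i in range(len(cent_a))
                            if i not in matched_a],
            "unmatched_b": [tuple(cent_b[i]) for i in range(len(cent_b))
                            if i not in matched_b],
        }
        return records, residuals
    return records


def apply_corrections(records: Sequence[FollicleRecord],
                      corrections: CorrectionSet) -> list[FollicleRecord]:
    """Apply a hand-authored correction set, returning a new table.

    Touched records get source='corrected'; applying the same set twice
    equals applying it once; unknown ids raise listing every offender.
    """
    out = {r.id: replace(r) for r in records}
    # the last action per follicle id wins (a hand-edited correction file's
    # final word), which also makes re-application idempotent: deletes are
    # no-ops on missing ids and adds overwrite with the same record
    final: dict[int, Correction] = {}
    for c in corrections.corrections:
        if c.action not in {"set_angle", "set_unpolarized", "delete", "add"}:
            raise ValueError(f"unknown correction action {c.action!r}")
        if c.follicle_id is None:
            raise ValueError("corrections require an explicit follicle id")
        final[c.follicle_id] = c

    bad = [fid for fid, c in final.items()
           if c.action in {"set_angle", "set_unpolarized"} and fid not in out]
    if bad:
        raise KeyError(f"corrections reference unknown follicle ids: {sorted(bad)}")

    for fid in sorted(final):
        c = final[fid]
        if c.action == "set_angle":
            out[fid] = replace(out[fid], angle=float(c.payload["angle"]),
                               polarized=True, source="corrected")
        elif c.action == "set_unpolarized":
            out[fid] = replace(out[fid], angle=UNDEFINED_ANGLE,
                               polarized=False, source="corrected")
        elif c.action == "delete":
            out.pop(fid, None)
        else:  # add
            p = c.payload
            out[fid] = FollicleRecord(
                fid, float(p["x"]), float(p["y"]),
                angle=float(p.get("angle", UNDEFINED_ANGLE)),
                polarized=bool(p.get("polarized", "angle" in p)),
                source="corrected")
    return [out[k] for k in sorted(out)]


def voronoi_orientation_map(records: Sequence[FollicleRecord],
                            extent: tuple[int, int],
                            cmap: str = "hsv",
                            render: bool = True):
    """Color-coded Voronoi diagram of follicle orientations.

    Each polygon marks one follicle and is filled with a cyclic colormap at
    its orientation (cool = anterior, warm = posterior); unpolarized
    polygons are black.  Returns (list of (record, shapely polygon, rgba),
    rendered raster or None).
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError("need at least 3 follicles for a Voronoi diagram")
    pts = np.array([(r.x, r.y) for r in records])
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("degenerate input: follicle positions are collinear")

    w, h = extent
    rect = box(0, 0, w, h)
    cells = voronoi_diagram(MultiPoint([Point(p) for p in pts]), envelope=rect)
    polys = []
    geoms = list(cells.geoms)
    tree = shapely.STRtree(geoms)
    for rec, p in zip(records, pts):
        i = int(tree.nearest(Point(p)))
        g = geoms[i]
        if not g.contains(Point(p)):  # fallback: scan
            g = next(gg for gg in geoms if gg.intersects(Point(p).buffer(1e-9)))
        clipped = g.intersection(rect)
        color = (0.0, 0.0, 0.0, 1.0) if not rec.polarized else \
            tuple(orientation_color(rec.angle, cmap))
        polys.append((rec, clipped, color))

    raster = None
    if render:
        raster = _rasterize_nearest(records, extent, cmap)
    return polys, raster


def _rasterize_nearest(records, extent, cmap):
    """Nearest-follicle (Voronoi) raster, RGBA float in [0,1]."""
    from scipy.spatial import cKDTree

    w, h = extent
    pts = np.array([(r.x, r.y) for r in records])
    tree = cKDTree(pts)
    xs, ys = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    _, idx = tree.query(np.column_stack([xs.ravel(), ys.ravel()]))
    colors = np.array([
        (0.0, 0.0, 0.0, 1.0) if not r.polarized
        else tuple(orientation_color(r.angle, cmap)) for r in records])
    return colors[idx].reshape(h, w, 4)
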