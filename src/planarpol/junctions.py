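"""Per-cell junctional polarity nematics and their spatial averaging.

A PCP protein such as Celsr1 is enriched on two antipodal arcs of the
cell boundary; the axis of that enrichment is a nematic (180°-periodic
director) with a magnitude.  Per cell, boundary pixel positions are
weighted by intensity and the principal axes of their second-moment
matrix give the director angle; the normalized moment anisotropy
(λ1−λ2)/(λ1+λ2) gives a bounded magnitude that is 0 for a uniform
boundary.  Nematics are pooled into magnitude-weighted circular
histograms and averaged over local neighborhoods in double-angle space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .conventions import angle_from_vector, wrap_axial

logger = logging.getLogger(__name__)

SENTINEL = float("nan")


@dataclass
class CellNematic:
    """One cell's junctional polarity: director angle in [0,180°) and a
    non-negative magnitude (0 = unpolarized boundary)."""

    cell_id: int
    x: float
    y: float
    angle: float  # [0, 180)
    magnitude: float  # >= 0

    def __post_init__(self):
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        self.angle = float(wrap_axial(self.angle))


@dataclass
class LocalNematicMap:
    """Locally averaged nematics plus the saturation scaling state."""

    cell_ids: np.ndarray
    centroids: np.ndarray  # (n, 2) x, y
    avg_angle: np.ndarray  # [0, 180), NaN where excluded
    avg_magnitude: np.ndarray
    radius: float
    saturation: np.ndarray | None = None


def cell_polarity_pca(mask: np.ndarray, intensity: np.ndarray,
                      boundary_width: int = 2, min_area: int = 16,
                      exclude_border: bool = True, n_sectors: int = 36):
    """Per-cell polarity nematic from a label mask and an intensity channel.

    For each cell, boundary-band pixels (within ``boundary_width`` of the
    cell border) are grouped into ``n_sectors`` equal angular sectors
    about the cell centroid; each sector's mean intensity weights its
    direction nematic, and the principal axis of the resulting
    second-moment matrix gives the director (folded to [0, 180°)) with
    magnitude (λ1−λ2)/(λ1+λ2).  Averaging per sector normalizes away the
    uneven angular sampling of a polygonal boundary, so a uniformly lit
    boundary of any cell shape scores magnitude 0 and the estimate
    reflects intensity polarity, not cell elongation.  Cells touching the
    image border have a partial boundary and are excluded.  Returns
    (nematics, excluded_ids).
    """
    if n_sectors % 4 != 0:
        raise ValueError("n_sectors must be a multiple of 4 (90-degree "
                         "rotation symmetry of the sector grid)")
    mask = np.asarray(mask)
    intensity = np.asarray(intensity, float)
    if mask.shape != intensity.shape:
        raise ValueError("mask and intensity must share an extent")
    h, w = mask.shape

    labels = np.unique(mask)
    labels = labels[labels > 0]
    border_labels = set(np.unique(np.concatenate([
        mask[0, :], mask[-1, :], mask[:, 0], mask[:, -1]]))) - {0}

    # boundary band: cell pixels within boundary_width of another label/bg
    same = np.ones_like(mask, dtype=bool)
    for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
        same &= np.roll(mask, sh, axis=ax) == mask
    edge = (mask > 0) & ~same
    if boundary_width > 1:
        near_edge = ndimage.distance_transform_edt(~edge) < boundary_width
    else:
        near_edge = edge
    band = (mask > 0) & near_edge

    areas = ndimage.sum_labels(np.ones_like(mask), mask, labels)
    coms = ndimage.center_of_mass(np.ones_like(mask), mask, labels)

    # group band pixels by label once instead of scanning per cell
    b_rows, b_cols = np.nonzero(band)
    b_labs = mask[b_rows, b_cols]
    order = np.argsort(b_labs, kind="stable")
    b_rows, b_cols, b_labs = b_rows[order], b_cols[order], b_labs[order]
    starts = np.searchsorted(b_labs, labels, side="left")
    stops = np.searchsorted(b_labs, labels, side="right")

    nematics, excluded = [], []
    for lab, area, (cy, cx), lo, hi in zip(labels, areas, coms, starts, stops):
        if (exclude_border and lab in border_labels) or area < min_area:
            excluded.append(int(lab))
            continue
        rows, cols = b_rows[lo:hi], b_cols[lo:hi]
        wgt = np.clip(intensity[rows, cols], 0.0, None)
        if wgt.sum() <= 0:
            nematics.append(CellNematic(int(lab), cx, cy, 0.0, 0.0))
            continue
        # biological angular position of each boundary pixel about the
        # cell centroid
        phi = np.deg2rad(angle_from_vector(cols - cx, rows - cy))
        sector = np.floor((phi + np.pi) / (2 * np.pi) * n_sectors).astype(int)
        sector = np.clip(sector, 0, n_sectors - 1)
        counts = np.bincount(sector, minlength=n_sectors).astype(float)
        sums = np.bincount(sector, weights=wgt, minlength=n_sectors)
        filled = counts > 0
        means = np.zeros(n_sectors)
        means[filled] = sums[filled] / counts[filled]
        total = means.sum()
        if total <= 0:
            nematics.append(CellNematic(int(lab), cx, cy, 0.0, 0.0))
            continue
        centers = -np.pi + (np.arange(n_sectors) + 0.5) * 2 * np.pi / n_sectors
        # double-angle resultant == (λ1−λ2)/(λ1+λ2) of the intensity-
        # weighted second-moment matrix of the sector direction nematics
        S = np.sum(means * np.exp(2j * centers)) / total
        mag = float(np.abs(S))
        ang = wrap_axial(np.rad2deg(np.angle(S)) / 2.0) if mag > 0 else 0.0
        nematics.append(CellNematic(int(lab), cx, cy, float(ang), mag))
    return nematics, excluded


def circular_histogram(nematics, n_bins: int = 18):
    """Magnitude-weighted circular histogram over [0°, 180°).

    Each cell contributes its magnitude to the bin containing its angle;
    total mass equals the magnitude sum.  Returns (masses, bin_edges).
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    angles = np.array([n.angle for n in nematics], float)
    mags = np.array([n.magnitude for n in nematics], float)
    masses, _ = np.histogram(angles, bins=edges, weights=mags)
    return masses, edges


def local_average_nematic(nematics, radius: float = 40.0) -> LocalNematicMap:
    """Average nematics over centroid neighborhoods in double-angle space.

    S = Σ_i m_i (cos 2θ_i, sin 2θ_i) / n over cells within ``radius``
    (self included); averaged magnitude = |S|, averaged angle =
    ½ atan2(Sy, Sx) folded to [0, 180°).  Orthogonal nematics of equal
    magnitude cancel exactly.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    nematics = list(nematics)
    ids = np.array([n.cell_id for n in nematics])
    pts = np.array([(n.x, n.y) for n in nematics], float)
    m = np.array([n.magnitude for n in nematics], float)
    two = np.deg2rad(2.0 * np.array([n.angle for n in nematics], float))
    cx, sx = m * np.cos(two), m * np.sin(two)

    tree = cKDTree(pts)
    avg_angle = np.empty(len(nematics))
    avg_mag = np.empty(len(nematics))
    for i in range(len(nematics)):
        idx = tree.query_ball_point(pts[i], radius)
        n_h = len(idx)
        Sx, Sy = cx[idx].sum() / n_h, sx[idx].sum() / n_h
        avg_mag[i] = np.hypot(Sx, Sy)
        avg_angle[i] = wrap_axial(np.rad2deg(np.arctan2(Sy, Sx)) / 2.0) \
            if avg_mag[i] > 0 else 0.0
    return LocalNematicMap(cell_ids=ids, centroids=pts, avg_angle=avg_angle,
                           avg_magnitude=avg_mag, radius=float(radius))


def saturation_scale(magnitudes: np.ndarray, clip_quantile: float = 0.01,
                     magnitude_floor: float = 0.02):
    """Exclusion + percentile saturation scaling of averaged magnitudes.

    Magnitudes below ``magnitude_floor`` are excluded (NaN); the rest are
    affinely mapped so the ``clip_quantile`` percentile goes to 0 and the
    1-``clip_quantile`` percentile to 1, clipped to [0, 1].  A degenerate
    (constant) distribution maps to 1 to stay visible.
    """
    m = np.asarray(magnitudes, float)
    sat = np.full_like(m, np.nan)
    keep = np.isfinite(m) & (m >= magnitude_floor)
    if not keep.any():
        warnings.warn("all cells below the magnitude floor; empty map",
                      stacklevel=2)
        return sat, keep
    lo = np.quantile(m[keep], clip_quantile)
    hi = np.quantile(m[keep], 1.0 - clip_quantile)
    if hi <= lo:
        sat[keep] = 1.0
    else:
        sat[keep] = np.clip((m[keep] - lo) / (hi - lo), 0.0, 1.0)
    return sat, keep


def saturation_scaled_map(nmap: LocalNematicMap, mask: np.ndarray | None = None,
                          clip_quantile: float = 0.01,
                          magnitude_floor: float = 0.02,
                          cmap: str = "hsv"):
    """Spatial map of local polarity: hue = averaged angle (cyclic over
    180°), saturation = percentile-scaled averaged magnitude; excluded
    cells get the sentinel (black).

    With a label ``mask``, returns an RGBA raster painting each cell;
    otherwise returns per-cell RGBA colors.  The updated map (with its
    ``saturation`` array) is returned alongside.
    """
    import matplotlib.colors as mcolors

    sat, keep = saturation_scale(nmap.avg_magnitude, clip_quantile,
                                 magnitude_floor)
    nmap.saturation = sat
    hues = np.mod(nmap.avg_angle, 180.0) / 180.0
    colors = np.zeros((len(sat), 4))
    colors[:, 3] = 1.0
    if keep.any():
        hsv = np.stack([hues[keep], sat[keep], np.ones(keep.sum())], axis=-1)
        colors[keep, :3] = mcolors.hsv_to_rgb(hsv)
    if mask is None:
        return colors, nmap
    raster = np.zeros(mask.shape + (4,))
    raster[..., 3] = 1.0
    lut = {cid: colors[i] for i, cid in enumerate(nmap.cell_ids)}
    for cid, col in lut.items():
        raster[mask == cid] = col
    return raster, nmap
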