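"""Pixel-intensity metrics: masked Pearson colocalization with nuclear
exclusion, and surface-to-total labeling ratios with exposure scaling and
reference-group normalization.

Colocalization between a membrane marker and a PCP protein is computed
over non-nuclear pixels only; the nuclear mask comes from a minimum-error
(Kittler–Illingworth) threshold on the nuclear stain.  Surface ratios
quantify how much of a tagged receptor reaches the plasma membrane:
extracellular-epitope signal over total (fluorescent-protein) signal per
cell, background-subtracted, corrected for the longer surface-channel
exposure, and normalized so the wild-type construct's mean is 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)


@dataclass
class ColocResult:
    pearson_r: float
    n_pixels: int
    mask_coverage: float  # fraction of pixels excluded by the mask

    def __post_init__(self):
        if not -1.0 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if self.n_pixels <= 1:
            raise ValueError("need more than one included pixel")


@dataclass
class SurfaceRatio:
    cell_id: int
    ratio: float  # surface/total after corrections, >= 0
    normalized_ratio: float | None = None
    saturated: bool = False


def _min_error_criterion(hist: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Kittler–Illingworth minimum-error criterion J(T) for every split of
    the histogram; entries are +inf where a side is empty/degenerate."""
    p = hist.astype(float)
    total = p.sum()
    w1 = np.cumsum(p)
    m1 = np.cumsum(p * centers)
    s1 = np.cumsum(p * centers ** 2)
    w2 = total - w1
    m2 = m1[-1] - m1
    s2 = s1[-1] - s1
    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = m1 / w1
        mu2 = m2 / w2
        var1 = s1 / w1 - mu1 ** 2
        var2 = s2 / w2 - mu2 ** 2
        P1, P2 = w1 / total, w2 / total
        J = 1.0 + 2.0 * (P1 * np.log(np.sqrt(np.maximum(var1, 0.0)))
                         + P2 * np.log(np.sqrt(np.maximum(var2, 0.0)))) \
            - 2.0 * (P1 * np.log(P1) + P2 * np.log(P2))
    bad = (w1 <= 0) | (w2 <= 0) | ~np.isfinite(J)
    J = np.where(bad, np.inf, J)
    return J


def min_error_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Minimum-error (Gaussian-mixture) threshold of an intensity image.

    Minimizes the Kittler–Illingworth classification-error criterion over
    all histogram splits; the returned value separates the two classes
    (pixel > threshold = high class).  Raises on a constant image.
    """
    img = np.asarray(image, float).ravel()
    lo, hi = img.min(), img.max()
    if lo == hi:
        raise ValueError("constant image: no threshold exists")
    hist, edges = np.histogram(img, bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    J = _min_error_criterion(hist, centers)
    t = int(np.argmin(J[:-1]))  # split after bin t
    return float(edges[t + 1])


def nuclear_exclusion_mask(nuclear_channel: np.ndarray):
    """Binary nuclear mask (True = nuclear, to be excluded) via the
    minimum-error threshold on the nuclear stain.  Returns (mask,
    threshold)."""
    thr = min_error_threshold(nuclear_channel)
    return np.asarray(nuclear_channel, float) > thr, thr


def masked_pearson(a: np.ndarray, b: np.ndarray,
                   exclude: np.ndarray | None = None) -> ColocResult:
    """Pearson correlation of two channels over non-excluded pixels."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("channels must share an extent")
    if exclude is None:
        exclude = np.zeros(a.shape, bool)
    exclude = np.asarray(exclude, bool)
    if exclude.shape != a.shape:
        raise ValueError("mask must share the channel extent")
    inc = ~exclude
    av, bv = a[inc], b[inc]
    if av.size < 2:
        raise ValueError("need at least 2 included pixels")
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("zero variance in an included channel")
    r = float(np.corrcoef(av, bv)[0, 1])
    return ColocResult(pearson_r=min(max(r, -1.0), 1.0), n_pixels=int(av.size),
                       mask_coverage=float(exclude.mean()))


def surface_ratio(surface_channel: np.ndarray, total_channel: np.ndarray,
                  exposure_scale: float = 1.0,
                  cells: np.ndarray | None = None,
                  saturation_level: float | None = None,
                  min_cell_area: int = 20):
    """Per-cell surface/total signal ratios.

    The cell mask comes from an auto (Otsu) threshold of the total
    channel unless a label mask is supplied.  Per channel, background
    (mean outside every cell mask) is subtracted from each cell's mean;
    the surface mean is divided by ``exposure_scale`` to undo the longer
    surface-channel exposure; ratio = corrected surface / corrected
    total.  Cells containing saturated surface pixels are flagged and
    excluded.  Returns a list of SurfaceRatio.
    """
    if exposure_scale <= 0:
        raise ValueError("exposure_scale must be > 0")
    surf = np.asarray(surface_channel, float)
    tot = np.asarray(total_channel, float)
    if surf.shape != tot.shape:
        raise ValueError("channels must share an extent")

    if cells is None:
        thr = threshold_otsu(tot) if np.ptp(tot) > 0 else tot.max()
        labels, n = ndimage.label(tot > thr)
        # drop speckle components from background noise straddling the
        # threshold, then relabel compactly
        if n:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                       np.arange(1, n + 1))
            keep = np.flatnonzero(sizes >= min_cell_area) + 1
            lut = np.zeros(n + 1, int)
            lut[keep] = np.arange(1, len(keep) + 1)
            labels = lut[labels]
            n = len(keep)
    else:
        labels = np.asarray(cells).astype(int)
        n = labels.max()
    if n == 0:
        warnings.warn("no cells found", stacklevel=2)
        return []

    outside = labels == 0
    bg_surf = float(surf[outside].mean()) if outside.any() else 0.0
    bg_tot = float(tot[outside].mean()) if outside.any() else 0.0

    out = []
    for cid in range(1, n + 1):
        sel = labels == cid
        if not sel.any():
            warnings.warn(f"cell {cid}: empty mask, skipped", stacklevel=2)
            continue
        saturated = bool(saturation_level is not None
                         and np.any(surf[sel] >= saturation_level))
        s = float(surf[sel].mean()) - bg_surf
        t = float(tot[sel].mean()) - bg_tot
        if s < 0 or t < 0:
            warnings.warn(f"cell {cid}: negative corrected intensity floored "
                          "at 0", stacklevel=2)
        s = max(s, 0.0) / exposure_scale
        t = max(t, 0.0)
        ratio = 0.0 if t == 0 else s / t
        out.append(SurfaceRatio(cell_id=cid, ratio=ratio, saturated=saturated))
    return out


def normalize_cohort(ratios, groups, reference: str):
    """Rescale every ratio so the reference group's mean becomes exactly 1.

    ``groups`` maps cell_id -> group label.  Saturated cells are excluded
    from the reference mean and carry no normalized value.
    """
    ref_vals = [r.ratio for r in ratios
                if groups[r.cell_id] == reference and not r.saturated]
    if not ref_vals:
        raise ValueError(f"no usable cells in reference group {reference!r}")
    mean_ref = float(np.mean(ref_vals))
    if mean_ref == 0:
        raise ValueError("reference group mean is 0; cannot normalize")
    for r in ratios:
        r.normalized_ratio = None if r.saturated else r.ratio / mean_ref
    return ratios
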