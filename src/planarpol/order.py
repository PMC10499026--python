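"""Local order parameter of a follicle orientation field.

For each focal follicle, the polarized follicles within a neighborhood
radius are collected (3×d in embryonic mode, where d is the mean minimum
neighbor distance, or a fixed radius — 200 px by default — in postnatal
mode) and the mean of cos(θj−θk) over all unordered pairs in the
neighborhood is mapped to [0, 1] by the fixed affine transform
(1+mean)/2, so parallel fields score exactly 1 and an antiparallel pair
exactly 0.  Neighborhoods with fewer than two polarized members carry a
sentinel (rendered black downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from scipy.spatial import cKDTree

SENTINEL_ORDER = float("nan")


@dataclass
class NeighborhoodSpec:
    """Neighborhood rule: embryonic = multiplier×d, postnatal = fixed radius."""

    mode: str = "embryonic"
    multiplier: float = 3.0
    fixed_radius: float = 200.0

    def __post_init__(self):
        if self.mode not in {"embryonic", "postnatal"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.multiplier <= 0 or self.fixed_radius <= 0:
            raise ValueError("multiplier and fixed_radius must be > 0")

    def radius(self, positions: np.ndarray) -> float:
        if self.mode == "postnatal":
            return float(self.fixed_radius)
        return self.multiplier * mean_min_neighbor_distance(positions)


@dataclass
class OrderRecord:
    follicle_id: int
    order: float  # in [0,1]; NaN sentinel when <2 polarized members
    n_neighbors: int
    radius_used: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.order)


def mean_min_neighbor_distance(positions: np.ndarray) -> float:
    """Mean over all follicles of the distance to the nearest neighbor (d)."""
    positions = np.asarray(positions, float)
    if len(positions) < 2:
        raise ValueError("need at least 2 positions")
    d, _ = cKDTree(positions).query(positions, k=2)
    return float(d[:, 1].mean())


def _pairwise_mean_cos(angles_deg: np.ndarray) -> float:
    """Mean of cos(θj−θk) over unordered pairs, via the resultant identity
    |Σ e^{iθ}|² = n + 2 Σ_{j<k} cos(θj−θk)."""
    a = np.deg2rad(angles_deg)
    n = len(a)
    res2 = np.cos(a).sum() ** 2 + np.sin(a).sum() ** 2
    return float((res2 - n) / (n * (n - 1)))


def local_order(records, spec: NeighborhoodSpec | None = None,
                pairs: str = "all") -> list[OrderRecord]:
    """Per-follicle local order values.

    ``pairs='all'`` (default) averages cos over all unordered pairs in the
    focal neighborhood (focal included); ``pairs='focal'`` averages only
    focal-vs-neighbor pairs.  Both agree on the parallel (1) and
    antiparallel-pair (0) anchors.  Unpolarized records are excluded from
    averaging but still receive an (undefined-order) output row.
    """
    if pairs not in {"all", "focal"}:
        raise ValueError("pairs must be 'all' or 'focal'")
    spec = spec or NeighborhoodSpec()
    records = list(records)
    pos = np.array([(r.x, r.y) for r in records])
    radius = spec.radius(pos)
    polarized = np.array([r.polarized for r in records])
    angles = np.array([r.angle if r.polarized else np.nan for r in records])

    tree = cKDTree(pos[polarized]) if polarized.any() else None
    pol_angles = angles[polarized]
    out = []
    for i, r in enumerate(records):
        if tree is None:
            out.append(OrderRecord(r.id, SENTINEL_ORDER, 0, radius))
            continue
        idx = tree.query_ball_point(pos[i], radius)
        hood = pol_angles[idx]
        if not r.polarized:
            # unpolarized focal keeps its map position but no order value
            out.append(OrderRecord(r.id, SENTINEL_ORDER, len(hood), radius))
            continue
        if len(hood) < 2:
            out.append(OrderRecord(r.id, SENTINEL_ORDER, len(hood), radius))
            continue
        if pairs == "all":
            c = _pairwise_mean_cos(hood)
        else:
            diffs = np.deg2rad(hood - r.angle)
            others = np.cos(diffs)
            # exclude the focal-with-itself pair
            c = float((others.sum() - 1.0) / (len(hood) - 1))
        out.append(OrderRecord(r.id, (1.0 + c) / 2.0, len(hood), radius))
    return out


def minmax_rescale(orders: np.ndarray) -> np.ndarray:
    """Per-image min-max rescale of defined order values to [0, 1]
    (alternative presentation scaling; the fixed affine map is the default
    because it anchors 0 to antiparallel and 1 to parallel on every
    dataset)."""
    o = np.asarray(orders, float)
    finite = np.isfinite(o)
    lo, hi = o[finite].min(), o[finite].max()
    out = o.copy()
    out[finite] = 0.0 if hi == lo else (o[finite] - lo) / (hi - lo)
    return out


def order_color(order: float, cmap: str = "Reds"):
    """White→red color for an order value (1 = white = high coordination,
    0 = dark red = antiparallel); sentinel → black."""
    if not np.isfinite(order):
        return (0.0, 0.0, 0.0, 1.0)
    return tuple(colormaps[cmap](1.0 - float(np.clip(order, 0.0, 1.0))))


def order_heatmap(order_records, records, extent, cmap: str = "Reds"):
    """Voronoi-style raster heat map of local order (white high, red low,
    black undefined/unpolarized)."""
    from scipy.spatial import cKDTree as _T

    w, h = extent
    pts = np.array([(r.x, r.y) for r in records])
    by_id = {o.follicle_id: o for o in order_records}
    colors = np.array([order_color(by_id[r.id].order, cmap) if r.id in by_id
                       else (0.0, 0.0, 0.0, 1.0) for r in records])
    tree = _T(pts)
    xs, ys = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    _, idx = tree.query(np.column_stack([xs.ravel(), ys.ravel()]))
    return colors[idx].reshape(h, w, 4)
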