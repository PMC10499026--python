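"""Ground-truth planar-polarity scene generation.

Every measurement stage in the package has a paired renderer here, so the
whole pipeline is testable by parameter recovery without any microscopy
data.  Scenes emulate the phenotype classes seen in embryonic back skin:
uniformly anterior follicle fields (wild type), a posteriorly reversed
patch with a sharp transition zone (the spontaneous reversal phenotype),
whorls, and fully random fields (PCP loss of function), plus an
unpolarized fraction that grows straight down.

Determinism contract: identical (parameters, seed) give bit-identical
scenes, images and tracks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .conventions import angle_from_vector, direction_vector, wrap_angle
from .follicles import UNDEFINED_ANGLE, FollicleRecord
from .tracks import Track

logger = logging.getLogger(__name__)

#: default wrapped-Gaussian angular spread of real follicle fields (degrees)
DEFAULT_ANGULAR_NOISE_SD = 10.0
#: default additive image noise as a fraction of the unit blob amplitude
DEFAULT_IMAGE_NOISE_SD = 0.05


class CapacityError(ValueError):
    """Requested point packing cannot fit in the extent."""


@dataclass
class PatternSpec:
    """Generative orientation pattern for a follicle field.

    kind: 'uniform' | 'reversed_patch' | 'whorl' | 'random'.
    base_angle: degrees, 0° = anterior (default).  reversed_patch assigns
    base_angle+180° strictly inside the patch and base_angle outside;
    inside a transition band of width ``transition_width`` straddling the
    patch edge, angles interpolate along the shortest circular arc and a
    fraction ``transition_unpolarized_fraction`` of follicles become
    unpolarized (the "growing straight down" zone).  whorl assigns the
    tangential (counterclockwise) direction around patch_center.
    """

    kind: str = "uniform"
    base_angle: float = 0.0
    patch_center: tuple[float, float] | None = None
    patch_radius: float = 0.0
    transition_width: float = 0.0
    transition_unpolarized_fraction: float = 0.0
    unpolarized_fraction: float = 0.0
    angular_noise_sd: float = DEFAULT_ANGULAR_NOISE_SD

    def __post_init__(self):
        if self.kind not in {"uniform", "reversed_patch", "whorl", "random"}:
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if not 0.0 <= self.unpolarized_fraction <= 1.0:
            raise ValueError("unpolarized_fraction must be in [0, 1]")
        if self.kind in {"reversed_patch", "whorl"} and self.patch_radius <= 0:
            raise ValueError(f"{self.kind} requires patch_radius > 0")

    def director(self, x, y):
        """Noise-free ground-truth angle (degrees) at position(s)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if self.kind == "uniform":
            return np.broadcast_to(wrap_angle(self.base_angle), x.shape).copy()
        if self.kind == "random":
            raise ValueError("random pattern has no deterministic director")
        cx, cy = self.patch_center
        dx, dy = x - cx, y - cy
        if self.kind == "whorl":
            # tangential: radial angle + 90° (counterclockwise swirl)
            radial = angle_from_vector(dx, dy)
            return wrap_angle(radial + 90.0)
        # reversed_patch
        r = np.hypot(dx, dy)
        inner = self.patch_radius - self.transition_width / 2.0
        outer = self.patch_radius + self.transition_width / 2.0
        ang = np.full_like(r, wrap_angle(self.base_angle))
        ang[r < inner] = wrap_angle(self.base_angle + 180.0)
        if self.transition_width > 0:
            band = (r >= inner) & (r <= outer)
            # shortest circular arc from reversed (inner edge) to base
            frac = (r[band] - inner) / (outer - inner)
            ang[band] = wrap_angle(self.base_angle + 180.0 * (1.0 - frac))
        return ang


@dataclass
class SyntheticScene:
    """Ground-truth bundle: follicle table, director field, rendered
    channels, optional tracks, and the seed that produced it."""

    extent: tuple[int, int]
    follicles: list[FollicleRecord] = field(default_factory=list)
    director_field: Callable | None = None
    images: dict[str, np.ndarray] = field(default_factory=dict)
    tracks: list[Track] | None = None
    seed: int = 0
    pattern: PatternSpec | None = None


def gen_follicle_positions(n: int, extent: tuple[int, int],
                           min_spacing: float = 0.0, seed: int = 0,
                           margin: float = 0.0,
                           max_rejections: int = 10_000) -> np.ndarray:
    """Dart-throwing (Poisson-disc-like) placement of n follicles.

    Points are uniform over the extent (inset by ``margin``), pairwise
    distance >= min_spacing; an explicit CapacityError is raised after the
    rejection budget rather than silently returning fewer points.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_spacing < 0:
        raise ValueError("min_spacing must be >= 0")
    w, h = extent
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise CapacityError("margin leaves no room inside the extent")
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    rejections = 0
    while len(pts) < n:
        cand = np.array([rng.uniform(margin, w - margin),
                         rng.uniform(margin, h - margin)])
        if pts and min_spacing > 0:
            d = np.linalg.norm(np.array(pts) - cand, axis=1)
            if d.min() < min_spacing:
                rejections += 1
                if rejections > max_rejections:
                    raise CapacityError(
                        f"cannot place {n} points at spacing {min_spacing} "
                        f"in extent {extent} ({len(pts)} placed)")
                continue
        pts.append(cand)
    return np.array(pts)


def gen_orientation_pattern(positions: np.ndarray, spec: PatternSpec,
                            seed: int = 0) -> list[FollicleRecord]:
    """Assign ground-truth orientations to follicle positions.

    Each position gets the pattern angle plus wrapped-Gaussian noise of sd
    ``angular_noise_sd``; round(unpolarized_fraction * n) follicles, chosen
    by seeded sampling without replacement, are flagged unpolarized.
    """
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions, float)
    n = len(positions)
    x, y = positions[:, 0], positions[:, 1]
    if spec.kind == "random":
        base = rng.uniform(-180.0, 180.0, size=n)
    else:
        base = np.asarray(spec.director(x, y), float)
    noisy = wrap_angle(base + rng.normal(0.0, spec.angular_noise_sd, size=n))

    unpol = np.zeros(n, dtype=bool)
    k = int(round(spec.unpolarized_fraction * n))
    if k:
        unpol[rng.choice(n, size=k, replace=False)] = True
    if spec.kind == "reversed_patch" and spec.transition_width > 0 \
            and spec.transition_unpolarized_fraction > 0:
        cx, cy = spec.patch_center
        r = np.hypot(x - cx, y - cy)
        band = np.flatnonzero(
            np.abs(r - spec.patch_radius) <= spec.transition_width / 2.0)
        kb = int(round(spec.transition_unpolarized_fraction * len(band)))
        if kb:
            unpol[rng.choice(band, size=kb, replace=False)] = True

    records = []
    for i in range(n):
        if unpol[i]:
            records.append(FollicleRecord(i, x[i], y[i], UNDEFINED_ANGLE,
                                          polarized=False, source="ground_truth"))
        else:
            records.append(FollicleRecord(i, x[i], y[i], float(noisy[i]),
                                          polarized=True, source="ground_truth"))
    return records


def _gauss_blob(shape, center, sigma_long, sigma_short, axis_deg):
    """Anisotropic Gaussian blob; axis_deg is the biological angle of the
    long axis.  Returns a float raster of peak amplitude 1."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = center
    u = direction_vector(axis_deg)  # (dx, dy) long axis
    dx, dy = xs - cx, ys - cy
    along = dx * u[0] + dy * u[1]
    across = -dx * u[1] + dy * u[0]
    return np.exp(-(along ** 2 / (2 * sigma_long ** 2)
                    + across ** 2 / (2 * sigma_short ** 2)))


def render_placode_image(follicles: Sequence[FollicleRecord],
                         extent: tuple[int, int],
                         blob_offset: float = 6.0,
                         blob_sigma: float = 4.0,
                         noise_sd: float = DEFAULT_IMAGE_NOISE_SD,
                         seed: int = 0) -> np.ndarray:
    """Render the two placode marker channels from a follicle table.

    Channel A (anterior marker) is a round Gaussian blob displaced by
    ``blob_offset`` along each record's orientation; channel B (posterior
    marker) is an offset anisotropic Gaussian (crescent stand-in) displaced
    oppositely.  Unpolarized records render both channels concentric.
    Returns a float array of shape (2, h, w).
    """
    if blob_offset <= 0 and any(f.polarized for f in follicles):
        raise ValueError("blob_offset must be > 0 for polarized records")
    w, h = extent
    chan_a = np.zeros((h, w))
    chan_b = np.zeros((h, w))

    pts = np.array([(f.x, f.y) for f in follicles]) if follicles else np.empty((0, 2))
    if len(pts) > 1:
        d = cKDTree(pts).query(pts, k=2)[0][:, 1]
        n_close = int(np.sum(d < 2 * blob_sigma))
        if n_close:
            warnings.warn(f"{n_close} follicles closer than 2x blob_sigma; "
                          "detector stress case", stacklevel=2)

    for f in follicles:
        if f.polarized:
            u = direction_vector(f.angle)
            ca = (f.x + blob_offset * u[0], f.y + blob_offset * u[1])
            cb = (f.x - blob_offset * u[0], f.y - blob_offset * u[1])
            chan_a += _gauss_blob((h, w), ca, blob_sigma, blob_sigma, 0.0)
            # crescent approximated by an anisotropic blob elongated
            # perpendicular to the follicle axis (centroid is what matters)
            chan_b += _gauss_blob((h, w), cb, 1.6 * blob_sigma, 0.8 * blob_sigma,
                                  f.angle + 90.0)
        else:
            chan_a += _gauss_blob((h, w), (f.x, f.y), blob_sigma, blob_sigma, 0.0)
            chan_b += _gauss_blob((h, w), (f.x, f.y), blob_sigma, blob_sigma, 0.0)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        chan_a = chan_a + rng.normal(0.0, noise_sd, chan_a.shape)
        chan_b = chan_b + rng.normal(0.0, noise_sd, chan_b.shape)
    return np.stack([chan_a, chan_b])


def gen_cell_tessellation(n_cells: int, extent: tuple[int, int],
                          seed: int = 0, jitter: float = 0.35) -> np.ndarray:
    """Voronoi label mask of n_cells from jittered hex-like grid seeds.

    Labels 1..n_cells, each a single connected (convex) region; a 1-px
    border frame is background 0.  Cell size is set by the extent.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    w, h = extent
    rng = np.random.default_rng(seed)
    # near-square grid of seeds covering the extent
    aspect = w / h
    nx = max(1, int(round(np.sqrt(n_cells * aspect))))
    ny = int(np.ceil(n_cells / nx))
    sx, sy = w / nx, h / ny
    seeds = []
    for j in range(ny):
        for i in range(nx):
            if len(seeds) >= n_cells:
                break
            seeds.append(((i + 0.5) * sx + rng.normal(0, jitter * sx),
                          (j + 0.5) * sy + rng.normal(0, jitter * sy)))
    seeds = np.clip(np.array(seeds[:n_cells]), [1, 1], [w - 2, h - 2])
    tree = cKDTree(seeds)
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    _, idx = tree.query(np.column_stack([xs.ravel() + 0.5, ys.ravel() + 0.5]))
    mask = (idx + 1).astype(np.int32).reshape(h, w)
    mask[0, :] = mask[-1, :] = 0
    mask[:, 0] = mask[:, -1] = 0
    _absorb_fragments(mask)
    return mask


def _absorb_fragments(mask: np.ndarray) -> None:
    """Reassign stray pixels disconnected from their label's main component
    (pixel discretization of thin Voronoi slivers) to an adjacent cell, so
    every label is a single connected region."""
    for lab in np.unique(mask):
        if lab == 0:
            continue
        comp, n = ndimage.label(mask == lab)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        for frag in range(1, n + 1):
            if frag == keep:
                continue
            rows, cols = np.nonzero(comp == frag)
            for r, c in zip(rows, cols):
                neigh = mask[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2].ravel()
                neigh = neigh[(neigh != lab) & (neigh != 0)]
                if len(neigh):
                    mask[r, c] = np.bincount(neigh).argmax()


def paint_junction_intensity(mask: np.ndarray, director,
                             strength: float = 0.8,
                             noise_sd: float = DEFAULT_IMAGE_NOISE_SD,
                             seed: int = 0,
                             base: float = 1.0,
                             junction_width: int = 2) -> np.ndarray:
    """Paint junctional marker intensity polarized along a director field.

    Boundary pixels of each cell get
    ``base*(1-strength) + base*strength*cos²(φ-θ)`` where φ is the pixel's
    angular position about its cell centroid and θ the local ground-truth
    director (axis; cos² makes the enrichment antipodal, as for a PCP
    protein enriched on the two AP-facing junctions).  Interior pixels are
    ~0 before noise.

    ``director`` is either a callable (x, y) -> degrees or a raster of
    degrees sampled at each cell centroid.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    mask = np.asarray(mask)
    h, w = mask.shape
    out = np.zeros((h, w), float)
    # boundary = cell pixel with a different 4-neighbor label
    shifted_same = np.ones_like(mask, dtype=bool)
    for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
        rolled = np.roll(mask, sh, axis=ax)
        shifted_same &= rolled == mask
    boundary = (mask > 0) & ~shifted_same
    if junction_width > 1:
        near = ndimage.distance_transform_edt(~boundary) < junction_width
        boundary = (mask > 0) & near

    labels = np.unique(mask)
    labels = labels[labels > 0]
    coms = ndimage.center_of_mass(np.ones_like(mask), mask, labels)  # (row,col)
    for lab, (cy, cx) in zip(labels, coms):
        if callable(director):
            theta = float(director(cx, cy))
        else:
            theta = float(np.asarray(director)[int(round(cy)), int(round(cx))])
        rows, cols = np.nonzero(boundary & (mask == lab))
        phi = np.rad2deg(np.arctan2(rows - cy, -(cols - cx)))  # biological angle
        val = base * (1 - strength) + base * strength * \
            np.cos(np.deg2rad(phi - theta)) ** 2
        out[rows, cols] = val
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, out.shape)
    return out


def gen_stripe_texture(extent: tuple[int, int], angle: float = 0.0,
                       period: float = 12.0, noise_sd: float = 0.0,
                       seed: int = 0) -> np.ndarray:
    """Sinusoidal stripe texture whose iso-intensity lines run along
    ``angle`` (biological degrees).  Test input for structure-tensor
    orientation estimation."""
    if period < 2:
        raise ValueError("period must be >= 2 px")
    w, h = extent
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    normal = direction_vector(angle + 90.0)
    phase = (xs * normal[0] + ys * normal[1]) * 2 * np.pi / period
    img = 0.5 + 0.5 * np.sin(phase)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img


def render_orientation_texture(director_raster: np.ndarray,
                               period: float = 12.0, noise_sd: float = 0.0,
                               seed: int = 0) -> np.ndarray:
    """Stripe texture following a locally varying axis field.

    Exact for piecewise-constant axial fields (pointwise projection onto
    the local stripe normal); approximate where the field curves.
    """
    ang = np.asarray(director_raster, float)
    h, w = ang.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    normal = direction_vector(ang + 90.0)
    phase = (xs * normal[..., 0] + ys * normal[..., 1]) * 2 * np.pi / period
    img = 0.5 + 0.5 * np.sin(phase)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img


def gen_tracks(pattern: str, n_cells: int = 40, n_timepoints: int = 60,
               extent: tuple[int, int] = (200, 200), seed: int = 0,
               speed: float = 0.5, noise_sd: float = 0.0):
    """Generate placode cell tracks.

    counter_rotational emulates the wild-type rearrangement: cells starting
    posterior of the placode center drift anteriorly and inward, anterior
    cells drift outward and posteriorly.  reversed is the same field
    mirrored along AP; static holds position up to noise.  Returns
    (tracks, info) where info records the ground-truth net-flow sign.
    """
    if pattern not in {"counter_rotational", "reversed", "static"}:
        raise ValueError(f"unknown track pattern {pattern!r}")
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    rng = np.random.default_rng(seed)
    w, h = extent
    cx, cy = w / 2.0, h / 2.0
    x0 = rng.uniform(0.15 * w, 0.85 * w, n_cells)
    y0 = rng.uniform(0.15 * h, 0.85 * h, n_cells)

    tracks = []
    for i in range(n_cells):
        xs = np.empty(n_timepoints)
        ys = np.empty(n_timepoints)
        x, y = x0[i], y0[i]
        if pattern == "static":
            vx = vy = 0.0
        elif x0[i] > cx:  # posterior: converge anteriorward (-x) and inward
            vx = -speed
            vy = -speed * 0.6 * np.sign(y0[i] - cy)
        else:  # anterior: swept outward (ML) with a weak posterior drift
            vx = 0.3 * speed
            vy = speed * np.sign(y0[i] - cy)
        for t in range(n_timepoints):
            xs[t], ys[t] = x, y
            x += vx + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            y += vy + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        if pattern == "reversed":
            # the reversal phenotype is, by construction, the wild-type
            # rearrangement field mirrored along the AP axis
            xs = w - xs
        tracks.append(Track(track_id=i, t=np.arange(n_timepoints, dtype=float),
                            x=xs, y=ys))
    info = {"pattern": pattern, "center": (cx, cy),
            "anteriorward": {"counter_rotational": True, "reversed": False,
                             "static": None}[pattern]}
    return tracks, info


def gen_coloc_pair(extent: tuple[int, int], target_r: float = 0.6,
                   nuclear_fraction: float = 0.2, seed: int = 0,
                   smooth_sigma: float = 2.0):
    """Two rasters with a requested masked Pearson correlation plus a
    nuclear mask.

    B = r·Ã + sqrt(1-r²)·Ñ where Ã and Ñ are standardized over the
    non-nuclear region and Ñ is residualized against Ã there, so the
    achieved masked correlation equals target_r to numerical precision.
    Both rasters are affinely rescaled to a positive intensity range.
    """
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target_r must be in [-1, 1]")
    w, h = extent
    rng = np.random.default_rng(seed)
    a = ndimage.gaussian_filter(rng.normal(size=(h, w)), smooth_sigma)
    noise = ndimage.gaussian_filter(rng.normal(size=(h, w)), smooth_sigma)
    nuc_field = ndimage.gaussian_filter(rng.normal(size=(h, w)), 4.0)
    thr = np.quantile(nuc_field, 1.0 - nuclear_fraction)
    nuclear = nuc_field > thr

    inc = ~nuclear
    az = (a - a[inc].mean()) / a[inc].std()
    nz = noise - noise[inc].mean()
    # residualize the noise against A over the included region
    nz = nz - (nz[inc] @ az[inc]) / (az[inc] @ az[inc]) * az
    nz = nz / nz[inc].std()
    b = target_r * az + np.sqrt(max(0.0, 1.0 - target_r ** 2)) * nz

    a_out = 100.0 + 20.0 * az
    b_out = 100.0 + 20.0 * b
    return a_out, b_out, nuclear


def make_scene(pattern: PatternSpec, n: int = 100,
               extent: tuple[int, int] = (512, 512),
               min_spacing: float = 25.0, seed: int = 0,
               blob_offset: float = 6.0, blob_sigma: float = 4.0,
               noise_sd: float = DEFAULT_IMAGE_NOISE_SD,
               render: bool = True) -> SyntheticScene:
    """Convenience bundle: positions -> orientations -> rendered channels."""
    rng = np.random.default_rng(seed)
    s_pos, s_ang, s_img = (int(rng.integers(2 ** 31)) for _ in range(3))
    margin = 3 * blob_sigma + blob_offset
    pos = gen_follicle_positions(n, extent, min_spacing, seed=s_pos, margin=margin)
    recs = gen_orientation_pattern(pos, pattern, seed=s_ang)
    scene = SyntheticScene(extent=extent, follicles=recs, seed=seed,
                           pattern=pattern)
    if pattern.kind != "random":
        scene.director_field = pattern.director
    if render:
        img = render_placode_image(recs, extent, blob_offset=blob_offset,
                                   blob_sigma=blob_sigma, noise_sd=noise_sd,
                                   seed=s_img)
        scene.images["pcad"] = img[0]
        scene.images["sox9"] = img[1]
    return scene
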