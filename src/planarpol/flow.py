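"""Postnatal hair-orientation flow fields from bright-field texture.

A Gaussian-windowed structure tensor estimates the local texture axis at
the points of a regular grid (one vector per follicle at suitable window
and grid spacing).  The axis is 180°-ambiguous; a human- or
ground-truth-authored binary flip mask converts it to a full 360° vector
field (white = add 180°), which is then color-mapped (cool anterior, warm
posterior).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.feature import structure_tensor

from .conventions import (angle_from_vector, orientation_color, wrap_angle,
                          wrap_axial90)


@dataclass
class FlowGrid:
    """Regular grid of orientation samples.

    axial_angle: degrees in [-90, 90), 180°-ambiguous texture axis.
    vector_angle: degrees in (-180, 180] after flip-mask disambiguation
    (NaN before).  coherence in [0, 1] is the confidence of the estimate.
    """

    xs: np.ndarray  # 1-D grid column coordinates (px)
    ys: np.ndarray  # 1-D grid row coordinates (px)
    axial_angle: np.ndarray  # (len(ys), len(xs))
    coherence: np.ndarray
    vector_angle: np.ndarray
    spacing: float
    image_shape: tuple[int, int]


def load_flip_mask(raster: np.ndarray) -> np.ndarray:
    """Binary flip mask: any nonzero pixel means 'flip by 180°'."""
    return np.asarray(raster) != 0


def structure_tensor_orientation(image: np.ndarray, local_window: float = 10.0,
                                 grid_spacing: int = 12) -> FlowGrid:
    """Local texture axis and coherence on a regular lattice.

    The structure tensor is smoothed with sigma = local_window/2; the
    eigenvector of the *smaller* eigenvalue gives the along-stripe axis.
    Coherence is (λ1−λ2)/(λ1+λ2) with λ1 ≥ λ2, 0 where both vanish.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if local_window < 2 or grid_spacing < 2:
        raise ValueError("window and grid spacing must be >= 2")
    h, w = image.shape
    if local_window > min(h, w):
        raise ValueError("local window larger than the image")

    sigma = local_window / 2.0
    Arr, Arc, Acc = structure_tensor(image, sigma=sigma, order="rc",
                                     mode="reflect")
    # inset the lattice by the smoothing support so no estimate leans on
    # pixels outside the image
    margin = max(grid_spacing // 2, int(np.ceil(2.0 * sigma)))
    xs = np.arange(margin, w - margin + 1, grid_spacing)
    ys = np.arange(margin, h - margin + 1, grid_spacing)
    if len(xs) == 0 or len(ys) == 0:
        raise ValueError("image too small for the window/grid combination")
    jrr = Arr[np.ix_(ys, xs)]
    jrc = Arc[np.ix_(ys, xs)]
    jcc = Acc[np.ix_(ys, xs)]

    # eigen-decomposition of [[jcc, jrc], [jrc, jrr]] in (x, y) ordering
    tr = jcc + jrr
    diff = jcc - jrr
    disc = np.sqrt(diff ** 2 + 4 * jrc ** 2)
    lam1 = (tr + disc) / 2.0
    lam2 = (tr - disc) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(tr > 1e-12, (lam1 - lam2) / np.where(tr > 1e-12, tr, 1.0), 0.0)

    # eigenvector of the smaller eigenvalue (along-stripe direction),
    # components in image coordinates (dx, dy)
    dx = -2 * jrc
    dy = diff + disc
    # the two rows of (J - λ2 I) give parallel eigenvectors; pick the
    # better-conditioned one, falling back to an arbitrary axis when the
    # tensor is isotropic (coherence 0 there anyway)
    alt = np.hypot(dx, dy) < 1e-12
    dx = np.where(alt, disc - diff, dx)
    dy = np.where(alt, -2 * jrc, dy)
    degenerate = np.hypot(dx, dy) < 1e-12
    dx = np.where(degenerate, 1.0, dx)
    dy = np.where(degenerate, 0.0, dy)
    axial = wrap_axial90(angle_from_vector(dx, dy))

    return FlowGrid(xs=xs, ys=ys, axial_angle=axial, coherence=coherence,
                    vector_angle=np.full_like(axial, np.nan),
                    spacing=float(grid_spacing), image_shape=(h, w))


def disambiguate_with_flipmask(grid: FlowGrid, mask: np.ndarray) -> FlowGrid:
    """360° vector field: add 180° to the axis where the mask is true.

    The mask is sampled at each grid point; result wrapped to (-180, 180].
    """
    mask = load_flip_mask(mask)
    if mask.shape[0] < grid.ys[-1] + 1 or mask.shape[1] < grid.xs[-1] + 1:
        raise ValueError("flip mask does not cover the grid extent")
    flips = mask[np.ix_(grid.ys, grid.xs)]
    vec = flip_vectors(grid.axial_angle, flips)
    return replace(grid, vector_angle=vec)


def flip_vectors(angles: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """Add 180° where flips is true, wrapping to (-180, 180].  Applying the
    same flips twice is the identity."""
    return wrap_angle(np.asarray(angles, float) + 180.0 * np.asarray(flips, bool))


def confident_points(grid: FlowGrid, floor: float = 0.1) -> np.ndarray:
    """Boolean mask of grid points whose coherence exceeds the floor; points
    below carry no usable vector and are skipped downstream."""
    return grid.coherence > floor


def flow_colormap(grid: FlowGrid, cmap: str = "hsv",
                  coherence_floor: float = 0.1) -> np.ndarray:
    """RGBA raster (one pixel per grid cell) of the disambiguated field:
    cyclic 360° colormap, cool anterior / warm posterior; low-coherence
    points black."""
    if np.all(np.isnan(grid.vector_angle)):
        raise ValueError("vector_angle not set; run disambiguate_with_flipmask")
    rgba = orientation_color(grid.vector_angle, cmap)
    rgba[~confident_points(grid, coherence_floor)] = (0.0, 0.0, 0.0, 1.0)
    return rgba


def grid_truth(grid: FlowGrid, director) -> np.ndarray:
    """Sample a ground-truth director (callable (x, y)->deg or raster) at
    the grid points, for round-trip evaluation."""
    if callable(director):
        X, Y = np.meshgrid(grid.xs.astype(float), grid.ys.astype(float))
        return np.asarray(director(X, Y), float)
    return np.asarray(director, float)[np.ix_(grid.ys, grid.xs)]
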