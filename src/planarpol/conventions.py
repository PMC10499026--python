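"""Angle and coordinate conventions shared by every module.

Image frame: origin top-left, x rightward, y downward (row = y, col = x).
Biological frame: anterior is towards the left of the image (-x), so an
orientation angle of 0° means "pointing anterior" and ±180° means
"pointing posterior"; positive angles turn counterclockwise when the image
is viewed the usual way up (biological y-up sense).

All conversions between the two frames live here.  Vector-valued angles
are stored in degrees in (-180, 180]; axis-valued (nematic) angles in
[0, 180) or, for structure-tensor output, [-90, 90).
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps


def wrap_angle(deg):
    """Wrap vector angles (degrees) to (-180, 180]."""
    m = np.mod(-np.asarray(deg, dtype=float) + 180.0, 360.0)
    m = np.where(m >= 360.0, 0.0, m)  # guard float mod returning the modulus
    return -(m - 180.0)


def wrap_axial(deg):
    """Wrap axis angles (degrees, 180°-periodic) to [0, 180)."""
    m = np.mod(np.asarray(deg, dtype=float), 180.0)
    return np.where(m >= 180.0, 0.0, m)


def wrap_axial90(deg):
    """Wrap axis angles (degrees, 180°-periodic) to [-90, 90)."""
    m = np.mod(np.asarray(deg, dtype=float) + 90.0, 180.0)
    return np.where(m >= 180.0, 0.0, m) - 90.0


def direction_vector(angle_deg):
    """Unit direction(s) in image pixel coordinates (dx, dy) for a
    biological angle.  0° -> (-1, 0) (anterior/left); +90° turns
    counterclockwise in the y-up biological sense, which is (0, +1) in
    image coordinates (y down)."""
    a = np.deg2rad(np.asarray(angle_deg, dtype=float))
    return np.stack([-np.cos(a), np.sin(a)], axis=-1)


def angle_from_vector(dx, dy):
    """Biological angle (degrees in (-180, 180]) of an image-frame vector.

    Inverse of :func:`direction_vector`."""
    return wrap_angle(np.rad2deg(np.arctan2(np.asarray(dy, float),
                                            -np.asarray(dx, float))))


def angular_difference(a, b):
    """Signed circular difference a-b wrapped to (-180, 180] (degrees)."""
    return wrap_angle(np.asarray(a, float) - np.asarray(b, float))


def axial_difference(a, b):
    """Absolute axis-to-axis difference in [0, 90] degrees."""
    d = np.mod(np.asarray(a, float) - np.asarray(b, float), 180.0)
    return np.minimum(d, 180.0 - d)


def circular_mean_abs_error(measured, truth):
    """Mean absolute circular deviation (degrees) between two vector-angle
    arrays."""
    return float(np.mean(np.abs(angular_difference(measured, truth))))


def orientation_color(angle_deg, cmap="hsv"):
    """Cyclic 360°-periodic color for a vector angle.

    Cool colors (cyan/blue) near 0° (anterior), warm colors (red/orange)
    near ±180° (posterior); color(θ) == color(θ+360°).
    """
    cm = colormaps[cmap]
    frac = np.mod(np.asarray(angle_deg, dtype=float) + 180.0, 360.0) / 360.0
    return cm(frac)


def axial_color(angle_deg, cmap="hsv"):
    """Cyclic 180°-periodic color for an axis angle (nematic)."""
    cm = colormaps[cmap]
    frac = np.mod(np.asarray(angle_deg, dtype=float), 180.0) / 180.0
    return cm(frac)
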