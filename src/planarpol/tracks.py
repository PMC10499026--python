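"""Placode cell-track kinematics: smoothing, AP-position coloring, and a
net-flow summary for classifying cell-rearrangement polarity.

Tracks are an input (manual or plugin tracking happens upstream); here
they are smoothed with a centered moving average, false-colored by initial
anterior-posterior position, and summarized by the mean displacement of
the initially-posterior versus initially-anterior cell groups.  In the
wild-type rearrangement, posterior cells converge and move anteriorly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from matplotlib import colormaps

logger = logging.getLogger(__name__)


@dataclass
class Track:
    """One cell trajectory: frame indices and pixel positions."""

    track_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def initial_x(self) -> float:
        return float(self.x[0])

    @property
    def n_samples(self) -> int:
        return len(self.t)


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with symmetric shrinking end windows: at
    index i the window half-width is min(i, n-1-i, (window-1)//2), so the
    first/last samples are untouched and a linear sequence is invariant."""
    n = len(v)
    k = (window - 1) // 2
    if k == 0 or n < 3:
        return v.copy()
    c = np.concatenate([[0.0], np.cumsum(v)])
    out = np.empty(n)
    for i in range(n):
        half = min(i, n - 1 - i, k)
        out[i] = (c[i + half + 1] - c[i - half]) / (2 * half + 1)
    return out


def smooth_tracks(tracks, window: int = 30):
    """Smooth x and y independently with a centered moving average.

    Even windows are incremented to stay centered; window=1 is the
    identity; tracks shorter than 2 samples pass through with a warning.
    Timestamps are unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        window += 1
    out = []
    for tr in tracks:
        if tr.n_samples < 2:
            logger.warning("track %d has <2 samples; passed through", tr.track_id)
            out.append(replace(tr))
            continue
        out.append(replace(tr, x=_moving_average(tr.x, window),
                           y=_moving_average(tr.y, window)))
    return out


def color_by_initial_position(tracks, cmap: str = "rainbow"):
    """Rainbow color per track by rank of its initial AP (x) position.

    Rank-based (permutation invariant); ties broken by initial y then id.
    Returns {track_id: rgba}.
    """
    if not tracks:
        raise ValueError("no tracks to color")
    keys = sorted(tracks, key=lambda tr: (tr.x[0], tr.y[0], tr.track_id))
    cm = colormaps[cmap]
    n = len(keys)
    return {tr.track_id: tuple(cm(i / max(n - 1, 1))) for i, tr in enumerate(keys)}


def net_flow_direction(tracks, placode_center=None):
    """Summarize placode rearrangement polarity from cell tracks.

    Cells are split by their initial AP side of the placode center
    (anterior is -x).  Per group, the mean total displacement vector and a
    convergence score (mean displacement component toward the center) are
    reported.  In the wild-type counter-rotation the posterior cells are
    the converging, anteriorly migrating group; in a reversed placode the
    anterior cells converge instead.  The ``anteriorward`` flag is True
    when the converging group is the posterior one, False when it is the
    anterior one, and None when undecidable (empty group, or no group
    converges).  This is an explicit, conservative surrogate for the
    visual classification of placode polarity.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks")
    if placode_center is None:
        placode_center = (float(np.mean([tr.x[0] for tr in tracks])),
                          float(np.mean([tr.y[0] for tr in tracks])))
    cx, cy = placode_center
    post = [tr for tr in tracks if tr.x[0] > cx]
    ant = [tr for tr in tracks if tr.x[0] <= cx]

    def mean_disp(group):
        if not group:
            return None
        d = np.array([[tr.x[-1] - tr.x[0], tr.y[-1] - tr.y[0]] for tr in group])
        return d.mean(axis=0)

    def convergence(group):
        """Mean displacement component toward the placode center."""
        if not group:
            return None
        scores = []
        for tr in group:
            to_center = np.array([cx - tr.x[0], cy - tr.y[0]])
            norm = np.linalg.norm(to_center)
            if norm == 0:
                continue
            d = np.array([tr.x[-1] - tr.x[0], tr.y[-1] - tr.y[0]])
            scores.append(float(d @ to_center / norm))
        return float(np.mean(scores)) if scores else None

    dp, da = mean_disp(post), mean_disp(ant)
    cp, ca = convergence(post), convergence(ant)
    if cp is None or ca is None or max(cp, ca) <= 0 or cp == ca:
        flag = None
    else:
        flag = bool(cp > ca)
    return {"posterior_mean_displacement": None if dp is None else tuple(dp),
            "anterior_mean_displacement": None if da is None else tuple(da),
            "posterior_convergence": cp, "anterior_convergence": ca,
            "anteriorward": flag,
            "n_posterior": len(post), "n_anterior": len(ant),
            "center": tuple(placode_center)}
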