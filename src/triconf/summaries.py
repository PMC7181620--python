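"""Psychometric summaries: sliding-window curves and hexagonal heat maps.

Experiments 1 and 3 are summarized as mean confidence versus horizontal
target position, computed with a 0.6-deg sliding window moved in 0.1-deg
steps — first per subject, then averaged across subjects (mean +/- s.e.m.).
Experiment 2 is summarized on the plane with non-overlapping hexagonal
windows of 0.25-deg radius (center-to-vertex, flat-top orientation, lattice
anchored at the origin) covering -3..+3 deg on both axes.

Model predictions use the identical windowing code path: the expected
confidence E[c | s; theta] is computed from the Monte-Carlo response
distribution on an evenly spaced grid of target positions (0.1-deg step)
and then windowed/binned exactly like the data, so data-model comparisons
are insensitive to any common binning detail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data import Dataset
from .design import CategoryConfiguration
from .likelihood import response_table
from .observer import ObserverParams

__all__ = [
    "PsychometricCurve",
    "HexMap",
    "psychometric_curve",
    "hex_map",
    "model_prediction_surface",
    "WINDOW_WIDTH",
    "WINDOW_STEP",
    "HEX_RADIUS",
]

WINDOW_WIDTH = 0.6
WINDOW_STEP = 0.1
HEX_RADIUS = 0.25

#: Default horizontal plotting ranges (deg) per experiment.
CURVE_RANGE = {1: (-3.5, 3.5), 3: (-5.0, 5.0)}
HEX_EXTENT = (-3.0, 3.0)

#: Windows with fewer trials than this are flagged (not dropped).
MIN_OCCUPANCY = 5


def sliding_window_mean(
    x: np.ndarray, values: np.ndarray, centers: np.ndarray, width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of ``values`` over points whose ``x`` lies within each window
    [center - width/2, center + width/2]; empty windows give NaN.

    Single source of truth for windowing: both the data path and the model
    prediction path call this function.
    """
    x = np.asarray(x, dtype=float)
    values = np.asarray(values, dtype=float)
    means = np.full(len(centers), np.nan)
    counts = np.zeros(len(centers), dtype=int)
    half = width / 2.0 + 1e-9  # tolerate float error at window boundaries
    for i, c in enumerate(centers):
        mask = (x >= c - half) & (x <= c + half)
        counts[i] = mask.sum()
        if counts[i]:
            means[i] = values[mask].mean()
    return means, counts


@dataclass
class PsychometricCurve:
    """Mean confidence versus horizontal target position.

    ``mean``/``sem`` are across-subject statistics of the per-subject
    windowed curves; windows empty for a subject are excluded from that
    window's average.  ``low_occupancy`` flags windows where any subject
    contributed fewer than :data:`MIN_OCCUPANCY` trials.
    """

    centers: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    per_subject: np.ndarray  # (n_subjects, n_centers)
    counts: np.ndarray  # (n_subjects, n_centers)
    window_width: float
    step: float

    @property
    def low_occupancy(self) -> np.ndarray:
        return (self.counts < MIN_OCCUPANCY).any(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center": self.centers,
                "mean_confidence": self.mean,
                "sem": self.sem,
                "n_trials": self.counts.sum(axis=0),
            }
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.errorbar(self.centers, self.mean, yerr=self.sem, **kwargs)
        ax.set_xlabel("target position (deg)")
        ax.set_ylabel("mean confidence")
        ax.set_ylim(1, 4)
        return ax


def psychometric_curve(
    datasets: Union[Dataset, Sequence[Dataset]],
    window_width: float = WINDOW_WIDTH,
    step: float = WINDOW_STEP,
    x_range: Optional[tuple[float, float]] = None,
    config_id: Optional[int] = None,
) -> PsychometricCurve:
    """Sliding-window mean confidence, per subject then across subjects.

    ``x_range`` defaults to the experiment's plotting range (+/-3.5 deg for
    Experiment 1, +/-5 deg for Experiment 3).  ``config_id`` restricts the
    curve to a single stimulus configuration.
    """
    if isinstance(datasets, Dataset):
        datasets = [datasets]
    if not datasets:
        raise ValueError("need at least one dataset")
    eid = datasets[0].experiment_id
    if x_range is None:
        x_range = CURVE_RANGE.get(eid, (-3.5, 3.5))
    lo, hi = x_range
    n_steps = int(round((hi - lo) / step))
    centers = lo + step * np.arange(n_steps + 1)
    per_subject = np.full((len(datasets), len(centers)), np.nan)
    counts = np.zeros((len(datasets), len(centers)), dtype=int)
    for i, ds in enumerate(datasets):
        trials = ds.trials
        if config_id is not None:
            trials = trials[trials["config"] == config_id]
        m, c = sliding_window_mean(
            trials["target_x"].to_numpy(dtype=float),
            trials["confidence"].to_numpy(dtype=float),
            centers,
            window_width,
        )
        per_subject[i], counts[i] = m, c
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_subject, axis=0)
        n_eff = np.sum(~np.isnan(per_subject), axis=0)
        sd = np.nanstd(per_subject, axis=0, ddof=1)
        sem = np.where(n_eff > 1, sd / np.sqrt(np.maximum(n_eff, 1)), 0.0)
        sem = np.where(n_eff > 0, sem, np.nan)
    return PsychometricCurve(
        centers=centers,
        mean=mean,
        sem=sem,
        per_subject=per_subject,
        counts=counts,
        window_width=window_width,
        step=step,
    )


# -- hexagonal binning -------------------------------------------------------

_SQRT3 = math.sqrt(3.0)


def _hex_axial(points: np.ndarray, size: float) -> np.ndarray:
    """Nearest flat-top hexagon (axial coordinates) for each 2-D point.

    Uses the standard cube-coordinate rounding, which partitions the plane:
    every point maps to exactly one hexagon center.
    """
    x, y = points[..., 0] / size, points[..., 1] / size
    q = (2.0 / 3.0) * x
    r = (-1.0 / 3.0) * x + (_SQRT3 / 3.0) * y
    # cube rounding
    s = -q - r
    rq, rr, rs = np.round(q), np.round(r), np.round(s)
    dq, dr, ds = np.abs(rq - q), np.abs(rr - r), np.abs(rs - s)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    rq = np.where(fix_q, -rr - rs, rq)
    rr = np.where(fix_r, -rq - rs, rr)
    return np.stack([rq, rr], axis=-1).astype(int)


def _hex_center(axial: np.ndarray, size: float) -> np.ndarray:
    q, r = axial[..., 0], axial[..., 1]
    return np.stack([1.5 * size * q, _SQRT3 * size * (r + q / 2.0)], axis=-1)


@dataclass
class HexMap:
    """Mean confidence over a hexagonal tiling of the stimulus plane."""

    centers: np.ndarray  # (n_hex, 2)
    mean: np.ndarray  # (n_hex,), NaN where unoccupied
    occupancy: np.ndarray  # (n_hex,), total trials per hexagon
    radius: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.centers[:, 0],
                "y": self.centers[:, 1],
                "mean_confidence": self.mean,
                "n_trials": self.occupancy,
            }
        )

    def plot(self, ax=None, cmap="viridis"):
        import matplotlib.pyplot as plt
        from matplotlib.collections import PolyCollection

        ax = ax or plt.gca()
        angles = np.arange(6) * np.pi / 3.0
        verts = self.radius * np.stack([np.cos(angles), np.sin(angles)], axis=-1)
        occupied = ~np.isnan(self.mean)
        polys = [self.centers[i] + verts for i in np.flatnonzero(occupied)]
        coll = PolyCollection(polys, array=self.mean[occupied], cmap=cmap)
        ax.add_collection(coll)
        ax.autoscale_view()
        ax.set_aspect("equal")
        ax.set_xlabel("x (deg)")
        ax.set_ylabel("y (deg)")
        return ax


def _lattice(extent: tuple[float, float], size: float) -> np.ndarray:
    """All hexagon axial coordinates whose centers fall inside the extent."""
    lo, hi = extent
    qmax = int(math.ceil(hi / (1.5 * size))) + 1
    rmax = int(math.ceil(hi / (_SQRT3 * size))) + qmax + 1
    qs, rs = np.meshgrid(np.arange(-qmax, qmax + 1), np.arange(-rmax, rmax + 1))
    axial = np.stack([qs.ravel(), rs.ravel()], axis=-1)
    centers = _hex_center(axial, size)
    inside = (
        (centers[:, 0] >= lo)
        & (centers[:, 0] <= hi)
        & (centers[:, 1] >= lo)
        & (centers[:, 1] <= hi)
    )
    return axial[inside]


def hex_map(
    datasets: Union[Dataset, Sequence[Dataset]],
    radius: float = HEX_RADIUS,
    extent: tuple[float, float] = HEX_EXTENT,
) -> HexMap:
    """Hexagonally binned mean confidence, averaged across subjects.

    Each trial is assigned to exactly one hexagon (nearest-center rule);
    per-hexagon means are computed per subject and then averaged across the
    subjects that have trials there.  Hexagons with no trials from any
    subject have NaN mean ('left white' when plotted).
    """
    if isinstance(datasets, Dataset):
        datasets = [datasets]
    axial = _lattice(extent, radius)
    keys = {tuple(a): i for i, a in enumerate(axial)}
    n_hex = len(axial)
    sums = np.zeros((len(datasets), n_hex))
    counts = np.zeros((len(datasets), n_hex), dtype=int)
    for i, ds in enumerate(datasets):
        pts = ds.positions
        conf = ds.trials["confidence"].to_numpy(dtype=float)
        ax_idx = _hex_axial(pts, radius)
        for a, c in zip(ax_idx, conf):
            j = keys.get(tuple(a))
            if j is not None:
                sums[i, j] += c
                counts[i, j] += 1
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        per_subject = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        any_occupied = counts.sum(axis=0) > 0
        mean = np.where(any_occupied, np.nanmean(per_subject, axis=0), np.nan)
    return HexMap(
        centers=_hex_center(axial, radius),
        mean=mean,
        occupancy=counts.sum(axis=0),
        radius=radius,
    )


def model_prediction_surface(
    config: CategoryConfiguration,
    params: ObserverParams,
    grid_step: float = WINDOW_STEP,
    summary_kind: str = "curve",
    x_range: Optional[tuple[float, float]] = None,
    extent: tuple[float, float] = HEX_EXTENT,
    n_mc: int = 2000,
    seed: int = 0,
    window_width: float = WINDOW_WIDTH,
    radius: float = HEX_RADIUS,
) -> Union[PsychometricCurve, HexMap]:
    """Model-predicted confidence surface, windowed like the data.

    Computes E[c | s; theta] from the Monte-Carlo response distribution on
    an evenly spaced grid (1-D for curves, 2-D for hex maps) and then
    applies the same sliding-window / hexagon-assignment code as the data
    path.
    """
    if summary_kind == "curve":
        if x_range is None:
            x_range = CURVE_RANGE.get(config.experiment_id, (-3.5, 3.5))
        lo, hi = x_range
        pad = window_width / 2.0
        grid_x = np.arange(lo - pad, hi + pad + grid_step / 2.0, grid_step)
        grid = np.column_stack([grid_x, np.zeros_like(grid_x)])
        tables = response_table(grid, config, params, n_mc=n_mc, seed=seed)
        expected = (tables.sum(axis=1) * np.arange(1, 5)).sum(axis=1)
        n_steps = int(round((hi - lo) / grid_step))
        centers = lo + grid_step * np.arange(n_steps + 1)
        mean, counts = sliding_window_mean(grid_x, expected, centers, window_width)
        return PsychometricCurve(
            centers=centers,
            mean=mean,
            sem=np.zeros_like(mean),
            per_subject=mean[None, :],
            counts=counts[None, :],
            window_width=window_width,
            step=grid_step,
        )
    if summary_kind == "hex":
        lo, hi = extent
        g = np.arange(lo, hi + grid_step / 2.0, grid_step)
        gx, gy = np.meshgrid(g, g)
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        tables = response_table(grid, config, params, n_mc=n_mc, seed=seed)
        expected = (tables.sum(axis=1) * np.arange(1, 5)).sum(axis=1)
        axial = _lattice(extent, radius)
        keys = {tuple(a): i for i, a in enumerate(axial)}
        sums = np.zeros(len(axial))
        counts = np.zeros(len(axial), dtype=int)
        for a, v in zip(_hex_axial(grid, radius), expected):
            j = keys.get(tuple(a))
            if j is not None:
                sums[j] += v
                counts[j] += 1
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return HexMap(
            centers=_hex_center(axial, radius), mean=mean, occupancy=counts, radius=radius
        )
    raise ValueError("summary_kind must be 'curve' or 'hex'")
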