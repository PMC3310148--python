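"""Reference-region Logan graphical analysis for dynamic PET.

The distribution volume ratio (DVR) of a target region relative to a
reference region (here, a cerebellar-cortex surrogate) is estimated as the
slope of the Logan plot

    y(t) = int_0^t C_T(u) du / C_T(t)   versus
    x(t) = int_0^t C_R(u) du / C_T(t),

which becomes linear at late times; the fit uses frames whose midpoint falls
at or after ``t_start`` (default 900 s, i.e. from 15 minutes to the end of
the scan).  Integrals are cumulative trapezoids over frame midpoints,
anchored at (0, 0).  An early-frame duration-weighted sum provides the
perfusion-like image on which the reference region is drawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .frames import FrameSchedule
from .images import DynamicImage
from .voi import VOI

logger = logging.getLogger(__name__)

__all__ = ["TAC", "LoganFit", "sum_frames", "extract_tac", "logan_slope",
           "dvr_image"]

#: Default start of the linear segment of the Logan plot, seconds.
DEFAULT_T_START = 900.0


@dataclass
class TAC:
    """A time-activity curve sampled at frame midpoints."""

    times: np.ndarray      # frame midpoints, s
    durations: np.ndarray  # frame durations, s
    values: np.ndarray     # mean activity per frame, arbitrary units

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.times) == len(self.durations) == len(self.values)):
            raise ValueError("times, durations and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @classmethod
    def from_schedule(cls, schedule: FrameSchedule, values) -> "TAC":
        return cls(schedule.midpoints, schedule.duration_array, values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class LoganFit:
    """Result of a Logan-plot linear fit."""

    dvr: float         # slope (unitless)
    intercept: float   # minutes
    r_squared: float
    n_points: int


def _cumulative_integral(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Trapezoidal integral from 0 to each sample time, anchored at (0, 0)."""
    t = np.concatenate([[0.0], times])
    v = np.concatenate([[0.0], values])
    dt = np.diff(t)
    return np.cumsum(dt * (v[1:] + v[:-1]) / 2.0)


def sum_frames(image: DynamicImage, t_start: float, t_end: float) -> np.ndarray:
    """Duration-weighted sum of the frames fully contained in [t_start, t_end).

    With the default 18-frame schedule and window [0, 360), exactly frames
    1-7 (the first six minutes, a perfusion-like image) are summed.
    """
    idx = image.schedule.frames_in_window(t_start, t_end)
    if idx.size == 0:
        raise ValueError(f"no whole frame inside [{t_start}, {t_end}) s")
    durs = image.schedule.duration_array[idx]
    return np.tensordot(image.data[..., idx], durs, axes=([3], [0]))


def extract_tac(image: DynamicImage, voi: VOI) -> TAC:
    """Per-frame mean over the VOI voxels, sampled at frame midpoints."""
    if voi.mask.shape != image.shape:
        raise ValueError("VOI grid does not match the image")
    if voi.n_voxels == 0:
        raise ValueError("VOI is empty")
    values = image.data[voi.mask].mean(axis=0)
    return TAC.from_schedule(image.schedule, values)


def _late_frames(times: np.ndarray, t_start: float) -> np.ndarray:
    return np.flatnonzero(times >= t_start)


def logan_slope(target: TAC, reference: TAC,
                t_start: float = DEFAULT_T_START) -> LoganFit:
    """Fit the Logan plot of a target TAC against a reference-region TAC.

    Returns the ordinary-least-squares slope (the DVR estimate), intercept
    (minutes), R^2 and the number of frames used.

    Raises
    ------
    ValueError
        If fewer than 2 frames have midpoint >= ``t_start``, or if the target
        activity is not strictly positive on a used frame.
    """
    if not np.allclose(target.times, reference.times):
        raise ValueError("target and reference TACs must share the schedule")
    use = _late_frames(target.times, t_start)
    if use.size < 2:
        raise ValueError(
            f"need >= 2 frames with midpoint >= {t_start} s, found {use.size}"
        )
    bad = use[target.values[use] <= 0]
    if bad.size:
        raise ValueError(
            f"non-positive target activity in used frame {int(bad[0])}"
        )
    int_t = _cumulative_integral(target.times, target.values)
    int_r = _cumulative_integral(reference.times, reference.values)
    ct = target.values[use]
    y = int_t[use] / ct
    x = int_r[use] / ct
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else float(max(0.0, 1.0 - np.sum(resid**2) / ss_tot))
    return LoganFit(float(slope), float(intercept) / 60.0, r2, int(use.size))


def dvr_image(image: DynamicImage, reference_voi: VOI,
              t_start: float = DEFAULT_T_START) -> np.ndarray:
    """Voxelwise Logan DVR map using the reference-region TAC as input.

    Voxels that cannot be fitted (non-positive activity in a used frame) are
    set to NaN and counted in the log rather than silently zeroed.
    """
    ref = extract_tac(image, reference_voi)
    times = image.schedule.midpoints
    use = _late_frames(times, t_start)
    if use.size < 2:
        raise ValueError(f"need >= 2 frames with midpoint >= {t_start} s")

    shape = image.shape
    flat = image.data.reshape(-1, image.schedule.n_frames)
    valid = np.all(flat[:, use] > 0, axis=1)
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.info("dvr_image: %d of %d voxels unfittable (flagged NaN)",
                    n_invalid, flat.shape[0])

    out = np.full(flat.shape[0], np.nan)
    if valid.any():
        tv = flat[valid]
        # cumulative trapezoid anchored at (0, 0), vectorized over voxels
        t = np.concatenate([[0.0], times])
        v = np.concatenate([np.zeros((tv.shape[0], 1)), tv], axis=1)
        dt = np.diff(t)
        int_t = np.cumsum(dt * (v[:, 1:] + v[:, :-1]) / 2.0, axis=1)
        int_r = _cumulative_integral(ref.times, ref.values)

        ct = tv[:, use]
        y = int_t[:, use] / ct
        x = int_r[np.newaxis, use] / ct
        n = use.size
        sx, sy = x.sum(axis=1), y.sum(axis=1)
        sxx, sxy = (x * x).sum(axis=1), (x * y).sum(axis=1)
        denom = n * sxx - sx * sx
        slope = np.where(denom != 0, (n * sxy - sx * sy) / denom, np.nan)
        out[valid] = slope
    return out.reshape(shape)
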