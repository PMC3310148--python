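"""Dynamic-PET frame schedules.

A schedule is the ordered list of (start, duration) pairs, in seconds, of the
emission frames of a dynamic acquisition.  The default schedule is the
18-frame, 125-minute protocol used throughout this package: six 30 s frames,
four 180 s frames, five 600 s frames and three 1200 s frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FrameSchedule", "default_schedule"]

#: (count, duration_s) blocks of the default 18-frame acquisition.
DEFAULT_FRAME_BLOCKS = ((6, 30.0), (4, 180.0), (5, 600.0), (3, 1200.0))


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping frame timing starting at t = 0.

    Parameters
    ----------
    durations : array-like of float
        Frame durations in seconds, all strictly positive.  Frame starts are
        implied: the first frame starts at 0 and frames are contiguous.
    """

    durations: tuple = field(default=None)

    def __post_init__(self):
        d = np.asarray(self.durations, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("schedule needs at least one frame")
        if np.any(d <= 0):
            raise ValueError("frame durations must be strictly positive")
        object.__setattr__(self, "durations", tuple(float(x) for x in d))

    # -- derived timing arrays -------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.durations)

    @property
    def duration_array(self) -> np.ndarray:
        return np.asarray(self.durations, dtype=float)

    @property
    def starts(self) -> np.ndarray:
        d = self.duration_array
        return np.concatenate([[0.0], np.cumsum(d)[:-1]])

    @property
    def ends(self) -> np.ndarray:
        return np.cumsum(self.duration_array)

    @property
    def midpoints(self) -> np.ndarray:
        return self.starts + self.duration_array / 2.0

    @property
    def total_duration(self) -> float:
        return float(self.duration_array.sum())

    # -- construction / IO ----------------------------------------------
    @classmethod
    def from_blocks(cls, blocks) -> "FrameSchedule":
        """Build from (count, duration_s) blocks, e.g. ``((6, 30.0), ...)``."""
        durations = []
        for count, dur in blocks:
            durations.extend([float(dur)] * int(count))
        return cls(tuple(durations))

    @classmethod
    def from_tsv(cls, path) -> "FrameSchedule":
        """Read a sidecar TSV with columns frame_start_s, frame_duration_s."""
        df = pd.read_csv(path, sep="\t")
        starts = df["frame_start_s"].to_numpy(float)
        durs = df["frame_duration_s"].to_numpy(float)
        sched = cls(tuple(durs))
        if not np.allclose(starts, sched.starts, atol=1e-6):
            raise ValueError("frames in TSV are not contiguous from t=0")
        return sched

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"frame_start_s": self.starts, "frame_duration_s": self.duration_array}
        ).to_csv(path, sep="\t", index=False)

    def frames_in_window(self, t_start: float, t_end: float) -> np.ndarray:
        """Indices of frames fully contained in [t_start, t_end)."""
        return np.flatnonzero(
            (self.starts >= t_start) & (self.ends <= t_end)
        )


def default_schedule() -> FrameSchedule:
    """The 18-frame / 7500 s (125 min) acquisition schedule."""
    return FrameSchedule.from_blocks(DEFAULT_FRAME_BLOCKS)
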