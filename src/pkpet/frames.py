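"""Acquisition frame schedules for dynamic PET.

A frame schedule is the list of reconstruction frame start times and
durations; it defines the time axis on which every time-activity curve
(TAC) lives. Frames must be contiguous and non-overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule"]


@dataclass(frozen=True)
class FrameSchedule:
    """Start times and durations of reconstruction frames, in seconds.

    Parameters
    ----------
    frame_start : array-like of float
        Frame start times in seconds, ordered.
    frame_duration : array-like of float
        Frame durations in seconds, strictly positive. Frames must tile
        the scan contiguously: ``start[i+1] == start[i] + duration[i]``.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        if start.ndim != 1 or dur.ndim != 1 or start.size != dur.size or start.size == 0:
            raise ValueError("frame_start and frame_duration must be equal-length 1-D arrays")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if not np.allclose(start[1:], start[:-1] + dur[:-1], rtol=0, atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_end(self) -> np.ndarray:
        """Frame end times in seconds."""
        return self.frame_start + self.frame_duration

    @property
    def total_seconds(self) -> float:
        return float(self.frame_end[-1] - self.frame_start[0])

    @property
    def mid_times_min(self) -> np.ndarray:
        """Frame midpoints in minutes (the TAC time axis)."""
        return (self.frame_start + 0.5 * self.frame_duration) / 60.0

    @property
    def durations_min(self) -> np.ndarray:
        return self.frame_duration / 60.0

    @classmethod
    def brain_60min(cls) -> "FrameSchedule":
        """The 22-frame, 60-minute brain protocol.

        4 x 15 s, 4 x 30 s, 3 x 60 s, 2 x 120 s, 8 x 300 s, 1 x 600 s
        (3600 s total).
        """
        dur = np.array(
            [15.0] * 4 + [30.0] * 4 + [60.0] * 3 + [120.0] * 2 + [300.0] * 8 + [600.0]
        )
        start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return cls(start, dur)
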