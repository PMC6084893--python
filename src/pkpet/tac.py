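"""Time-activity curves and interval integration."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = ["TimeActivityCurve", "auc", "UNITS"]

UNITS = ("kBq/mL", "SUV")


class TacDomainError(ValueError):
    """Raised when a TAC operation is requested outside the curve's support."""


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-frame mean activity of a region, voxel, or blood pool.

    Parameters
    ----------
    mid_times : array of float
        Frame midpoints in minutes, strictly increasing.
    values : array of float
        Activity at each midpoint, in the unit given by ``unit``.
    unit : str
        One of ``"kBq/mL"`` or ``"SUV"``.
    weights : array of float, optional
        Per-frame weights for fitting (constant weights if omitted).
    """

    mid_times: np.ndarray
    values: np.ndarray
    unit: str = "kBq/mL"
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.mid_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size or t.size == 0:
            raise ValueError("mid_times and values must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("mid_times must be strictly increasing")
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}")
        w = self.weights
        if w is not None:
            w = np.asarray(w, dtype=float)
            if w.shape != v.shape:
                raise ValueError("weights must match values in shape")
        object.__setattr__(self, "mid_times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.mid_times.size

    def scaled(self, factor: float) -> "TimeActivityCurve":
        """Return a copy with values multiplied by ``factor``."""
        return replace(self, values=self.values * factor)

    def to_suv(self, injected_dose_MBq: float, body_weight_kg: float) -> "TimeActivityCurve":
        """Convert kBq/mL to SUV assuming tissue density 1 g/mL.

        SUV = concentration / (injected dose / body weight), with the dose
        expressed in kBq and the weight in grams.
        """
        if self.unit != "kBq/mL":
            raise ValueError("to_suv requires a kBq/mL curve")
        norm = injected_dose_MBq * 1e3 / (body_weight_kg * 1e3)  # kBq/g
        return replace(self, values=self.values / norm, unit="SUV")


def auc(tac: TimeActivityCurve, t0: float, t1: float) -> float:
    """Trapezoidal area under the curve over [t0, t1] minutes.

    The curve is treated as piecewise linear between frame midpoints and is
    interpolated to the exact interval endpoints. The integration range is
    the overlap of [t0, t1] with the curve's support; an empty overlap is a
    domain error.
    """
    if not t0 < t1:
        raise TacDomainError("t0 must be less than t1")
    lo = max(t0, float(tac.mid_times[0]))
    hi = min(t1, float(tac.mid_times[-1]))
    if lo >= hi:
        raise TacDomainError(
            f"[{t0}, {t1}] min does not overlap the TAC support "
            f"[{tac.mid_times[0]:g}, {tac.mid_times[-1]:g}] min"
        )
    inside = (tac.mid_times > lo) & (tac.mid_times < hi)
    grid = np.concatenate([[lo], tac.mid_times[inside], [hi]])
    vals = np.interp(grid, tac.mid_times, tac.values)
    return float(np.trapezoid(vals, grid))
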