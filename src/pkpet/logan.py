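"""Logan graphical analysis: blood-input V_T and reference-tissue BP_ND.

For a reversible tracer, the Logan transform

    Y(T) = int_0^T C_t dt / C_t(T),   X(T) = int_0^T C_p dt / C_t(T)

becomes linear for T beyond an equilibration time t*, with slope V_T (the
total distribution volume). The reference-tissue variant replaces the
plasma integral with the reference-region integral (optionally plus
C_ref(T)/k2'), giving slope DVR and BP_ND = DVR - 1.

Models follow the statsmodels convention: construct from data, call
``fit()`` to obtain a results object with estimates, uncertainties and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import statsmodels.api as sm

from .input_function import InputFunction
from .tac import TimeActivityCurve

__all__ = [
    "LoganConfig",
    "LoganModel",
    "ReferenceLoganModel",
    "LoganResults",
    "logan_vt",
    "reference_logan_bpnd",
    "logan_diagnostics",
    "InsufficientPointsError",
]


class InsufficientPointsError(ValueError):
    """Fewer frames beyond t* than the configured minimum."""


@dataclass(frozen=True)
class LoganConfig:
    """Fit-window and weighting configuration.

    t_star: start of the linear window in minutes (frames with midpoint
    >= t_star are fitted). weighting: only "constant" is implemented.
    """

    t_star: float = 30.0
    weighting: str = "constant"
    min_points: int = 3

    def __post_init__(self) -> None:
        if self.min_points < 3:
            raise ValueError("min_points must be >= 3")
        if self.weighting != "constant":
            raise ValueError("only constant weighting is implemented")


def cumulative_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Cumulative trapezoid of a TAC at its midpoints, anchored at (0, 0).

    The initial triangle from t = 0 to the first midpoint is included,
    reducing early-frame discretization error in the Logan integrals.
    """
    t = np.concatenate([[0.0], tac.mid_times])
    v = np.concatenate([[0.0], tac.values])
    return np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))


def _blood_integral(blood, t: np.ndarray) -> np.ndarray:
    if isinstance(blood, InputFunction):
        return blood.integral(t)
    cum = cumulative_integral(blood)
    if not np.allclose(t, blood.mid_times):
        raise ValueError("blood TAC must share the tissue time axis")
    return cum


@dataclass(frozen=True)
class LoganResults:
    """Graphical-fit results.

    ``slope`` is V_T for a blood-input fit and DVR for a reference fit
    (``bp_nd = slope - 1`` is defined only for reference fits).
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n_points: int
    r_squared: float
    residuals: np.ndarray
    x: np.ndarray
    y: np.ndarray
    times: np.ndarray  # frame midpoints (min) of the fitted points
    kind: str  # "blood" or "reference"
    t_star: float

    @property
    def vt(self) -> float:
        if self.kind != "blood":
            raise AttributeError("V_T is defined only for blood-input fits")
        return self.slope

    @property
    def dvr(self) -> float:
        if self.kind != "reference":
            raise AttributeError("DVR is defined only for reference fits")
        return self.slope

    @property
    def bp_nd(self) -> float:
        if self.kind != "reference":
            raise AttributeError("BP_ND is defined only for reference fits")
        return self.slope - 1.0

    def summary(self) -> str:
        name = "V_T" if self.kind == "blood" else "DVR"
        lines = [
            f"Logan graphical fit ({self.kind} input), t* = {self.t_star:g} min",
            f"  n points    : {self.n_points}",
            f"  {name:<12}: {self.slope:.4f} (SE {self.slope_se:.4f})",
            f"  intercept   : {self.intercept:.4f} (SE {self.intercept_se:.4f})",
            f"  R^2         : {self.r_squared:.6f}",
        ]
        if self.kind == "reference":
            lines.insert(3, f"  BP_ND       : {self.bp_nd:.4f}")
        return "\n".join(lines)


class _GraphicalModel:
    """Shared OLS machinery for both Logan variants."""

    kind = "blood"

    def __init__(self, tissue: TimeActivityCurve, config: Optional[LoganConfig] = None):
        self.tissue = tissue
        self.config = config or LoganConfig()
        if self.config.t_star > tissue.mid_times[-1]:
            raise ValueError("t_star lies beyond the scan")

    def _transform(self):  # -> (x, y) at all frame midpoints
        raise NotImplementedError

    def fit(self) -> LoganResults:
        t = self.tissue.mid_times
        window = t >= self.config.t_star
        n = int(window.sum())
        if n < self.config.min_points:
            raise InsufficientPointsError(
                f"{n} frames at or after t* = {self.config.t_star} min "
                f"(need {self.config.min_points})"
            )
        if np.any(self.tissue.values[window] <= 0):
            raise ValueError("tissue TAC must be positive within the fit window")
        x_all, y_all = self._transform()
        x, y = x_all[window], y_all[window]
        X = sm.add_constant(x)
        res = sm.OLS(y, X).fit()
        return LoganResults(
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            slope_se=float(res.bse[1]),
            intercept_se=float(res.bse[0]),
            n_points=n,
            r_squared=float(res.rsquared),
            residuals=np.asarray(res.resid),
            x=x,
            y=y,
            times=t[window],
            kind=self.kind,
            t_star=self.config.t_star,
        )


class LoganModel(_GraphicalModel):
    """Blood-input Logan graphical model; ``fit()`` estimates V_T.

    ``input_function`` may be a fitted :class:`InputFunction` (integrated
    analytically) or a blood TAC on the tissue time axis (cumulative
    trapezoid anchored at zero).
    """

    kind = "blood"

    def __init__(
        self,
        tissue: TimeActivityCurve,
        input_function: Union[InputFunction, TimeActivityCurve],
        config: Optional[LoganConfig] = None,
    ):
        super().__init__(tissue, config)
        self.input_function = input_function

    def _transform(self):
        t = self.tissue.mid_times
        ct = self.tissue.values
        int_cp = _blood_integral(self.input_function, t)
        int_ct = cumulative_integral(self.tissue)
        with np.errstate(divide="ignore", invalid="ignore"):
            return int_cp / ct, int_ct / ct


class ReferenceLoganModel(_GraphicalModel):
    """Reference-tissue Logan model; ``fit()`` estimates DVR and BP_ND.

    With ``k2_prime`` (reference-region efflux constant, 1/min) supplied,
    X(T) = [int_0^T C_ref dt + C_ref(T)/k2'] / C_t(T); without it the
    C_ref/k2' term is omitted (adequate when the reference equilibrates
    quickly relative to t*).
    """

    kind = "reference"

    def __init__(
        self,
        target: TimeActivityCurve,
        reference: TimeActivityCurve,
        config: Optional[LoganConfig] = None,
        k2_prime: Optional[float] = None,
    ):
        super().__init__(target, config)
        if not np.allclose(reference.mid_times, target.mid_times):
            raise ValueError("target and reference must share the time axis")
        if np.any(reference.values <= 0):
            raise ValueError("reference TAC must be positive")
        if k2_prime is not None and k2_prime <= 0:
            raise ValueError("k2_prime must be positive")
        self.reference = reference
        self.k2_prime = k2_prime

    def _transform(self):
        ct = self.tissue.values
        int_ref = cumulative_integral(self.reference)
        num = int_ref.copy()
        if self.k2_prime is not None:
            num = num + self.reference.values / self.k2_prime
        int_ct = cumulative_integral(self.tissue)
        with np.errstate(divide="ignore", invalid="ignore"):
            return num / ct, int_ct / ct


def logan_vt(
    tissue: TimeActivityCurve,
    blood: Union[InputFunction, TimeActivityCurve],
    config: Optional[LoganConfig] = None,
) -> LoganResults:
    """Blood-input Logan V_T (convenience wrapper over :class:`LoganModel`)."""
    return LoganModel(tissue, blood, config).fit()


def reference_logan_bpnd(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    config: Optional[LoganConfig] = None,
    k2_prime: Optional[float] = None,
) -> LoganResults:
    """Reference-Logan BP_ND (wrapper over :class:`ReferenceLoganModel`)."""
    return ReferenceLoganModel(target, reference, config, k2_prime).fit()


@dataclass(frozen=True)
class LoganDiagnostics:
    max_relative_deviation: float
    adequacy_time_min: Optional[float]  # earliest time after which dev < 10%


def logan_diagnostics(
    fit: LoganResults, threshold: float = 0.10
) -> LoganDiagnostics:
    """t* adequacy check on a graphical fit.

    Reports the maximum relative deviation of the included points from the
    fitted line (relative to the fitted value) and the earliest included
    midpoint-ordinate after which every deviation stays below ``threshold``.
    """
    yhat = fit.intercept + fit.slope * fit.x
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.abs(fit.y - yhat) / np.maximum(np.abs(yhat), 1e-300)
    max_dev = float(np.max(dev)) if dev.size else 0.0
    # earliest fitted midpoint from which every later deviation < threshold
    adequacy = None
    for i in range(dev.size):
        if np.all(dev[i:] < threshold):
            adequacy = float(fit.times[i])
            break
    return LoganDiagnostics(max_relative_deviation=max_dev, adequacy_time_min=adequacy)
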