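"""Arterial/whole-blood input-function model.

The blood concentration C_p(t) is represented as a piecewise-linear curve
up to the peak followed by a three-component exponential decay:

    C_p(t) = linear interpolation of nodes,              t <= t_peak
    C_p(t) = sum_i A_i * exp(-lambda_i * (t - t_peak)),  t >  t_peak

with A_i >= 0 (kBq/mL) and lambda_i > 0 (1/min), continuous at the peak.
The tracer considered here is >98% plasma protein bound, so whole blood is
taken as the plasma concentration; a constant parent-fraction multiplier is
exposed for a population-average metabolite correction (default 1, i.e. no
correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .tac import TimeActivityCurve

__all__ = ["InputFunction", "BloodFitError", "fit_blood_model"]


class BloodFitError(RuntimeError):
    """Tri-exponential blood fit failed; carries residual diagnostics."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class InputFunction:
    """Piecewise-linear-rise / tri-exponential-decay blood curve.

    Parameters
    ----------
    prepeak_times, prepeak_values : arrays
        Nodes of the pre-peak piecewise-linear segment, in minutes and
        kBq/mL. The last node is the peak. If the first node is not at
        t = 0, the curve rises linearly from (0, 0).
    amplitudes : array of 3 floats
        Post-peak exponential amplitudes A_i (kBq/mL), non-negative and
        summing to the peak value (continuity).
    rates : array of 3 floats
        Decay rates lambda_i (1/min), strictly positive.
    parent_fraction : float
        Constant multiplier applied on evaluation (population metabolite
        correction; default 1.0).
    """

    prepeak_times: np.ndarray
    prepeak_values: np.ndarray
    amplitudes: np.ndarray
    rates: np.ndarray
    parent_fraction: float = 1.0

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.prepeak_times, dtype=float))
        v = np.atleast_1d(np.asarray(self.prepeak_values, dtype=float))
        A = np.asarray(self.amplitudes, dtype=float)
        lam = np.asarray(self.rates, dtype=float)
        if t.size != v.size or t.size == 0:
            raise ValueError("prepeak node times and values must match and be non-empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("prepeak node times must be strictly increasing")
        if t[0] < 0:
            raise ValueError("prepeak nodes must have t >= 0")
        if np.any(v < 0):
            raise ValueError("prepeak node values must be non-negative")
        if A.shape != (3,) or lam.shape != (3,):
            raise ValueError("exactly three exponential components are required")
        if np.any(A < 0) or np.any(lam <= 0):
            raise ValueError("amplitudes must be >= 0 and rates > 0")
        if not np.isclose(A.sum(), v[-1], rtol=1e-6, atol=1e-9):
            raise ValueError("sum of amplitudes must equal the peak value (continuity)")
        # prepend an implicit (0, 0) origin node when the curve starts later
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
            v = np.concatenate([[0.0], v])
        object.__setattr__(self, "prepeak_times", t)
        object.__setattr__(self, "prepeak_values", v)
        object.__setattr__(self, "amplitudes", A)
        object.__setattr__(self, "rates", lam)

    @property
    def t_peak(self) -> float:
        """Peak time in minutes."""
        return float(self.prepeak_times[-1])

    @property
    def peak_value(self) -> float:
        return float(self.prepeak_values[-1]) * self.parent_fraction

    def scaled(self, factor: float) -> "InputFunction":
        """Return a copy with all concentrations multiplied by ``factor``."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return replace(
            self,
            prepeak_values=self.prepeak_values * factor,
            amplitudes=self.amplitudes * factor,
        )

    def __call__(self, t) -> np.ndarray:
        """Evaluate C_p at times ``t`` (minutes, scalar or array)."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.interp(t, self.prepeak_times, self.prepeak_values)
        post = t > self.t_peak
        if np.any(post):
            dt = t[post] - self.t_peak
            out[post] = np.exp(-np.outer(dt, self.rates)) @ self.amplitudes
        out = out * self.parent_fraction
        return float(out[0]) if scalar else out

    def integral(self, t) -> np.ndarray:
        """Analytic cumulative integral of C_p from 0 to ``t`` (activity*min)."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        nt, nv = self.prepeak_times, self.prepeak_values
        # cumulative trapezoid at the nodes (exact: segments are linear)
        node_cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (nv[1:] + nv[:-1]) * np.diff(nt))]
        )
        tp = self.t_peak
        tc = np.clip(t, nt[0], tp)
        j = np.clip(np.searchsorted(nt, tc, side="right") - 1, 0, nt.size - 2)
        vt = np.interp(tc, nt, nv)
        out = node_cum[j] + 0.5 * (nv[j] + vt) * (tc - nt[j])
        post = t > tp
        if np.any(post):
            dt = t[post] - tp
            tails = (-np.expm1(-np.outer(dt, self.rates))) @ (self.amplitudes / self.rates)
            out[post] = node_cum[-1] + tails
        out = out * self.parent_fraction
        return float(out[0]) if scalar else out

    def node_times(self) -> np.ndarray:
        """Times (minutes) where the curve has slope discontinuities."""
        return self.prepeak_times.copy()


def _triexp(t, A, lam):
    return np.exp(-np.outer(t, lam)) @ A


def fit_blood_model(samples: TimeActivityCurve, n_restarts: int = 5, seed: int = 7) -> InputFunction:
    """Fit the blood model to sampled whole-blood (or IDIF) data.

    Pre-peak: the samples up to the peak are kept as linear-interpolation
    nodes (the peak node takes the fitted curve's value so the model is
    exactly continuous). Post-peak: a three-component exponential is fitted
    by non-negative nonlinear least squares with multistart restarts from
    log-spaced rate triples.

    Raises
    ------
    BloodFitError
        If the peak is at the last sample (no post-peak support), there are
        fewer than 8 post-peak samples, or no restart converges to a
        bounded-residual fit.
    """
    t = samples.mid_times
    y = samples.values
    ipk = int(np.argmax(y))
    post_t = t[ipk:] - t[ipk]
    post_y = y[ipk:]
    if post_t.size < 2:
        raise BloodFitError("peak at the last sample: no post-peak support")
    if post_t.size < 8:
        raise BloodFitError(f"need >= 8 post-peak samples, got {post_t.size}")
    peak = float(y[ipk])

    def resid(p):
        A, lam = p[:3], p[3:]
        return _triexp(post_t, A, lam) - post_y

    rng = np.random.default_rng(seed)
    base_rates = np.array([2.0, 0.3, 0.02])  # fast / medium / slow (1/min)
    best = None
    lb = np.concatenate([np.zeros(3), np.full(3, 1e-5)])
    ub = np.concatenate([np.full(3, 10 * peak + 1e-9), np.full(3, 50.0)])
    for k in range(n_restarts):
        jitter = 1.0 if k == 0 else rng.lognormal(0.0, 0.4, size=3)
        lam0 = np.clip(base_rates * jitter, lb[3:], ub[3:])
        A0 = np.clip(np.array([0.5, 0.35, 0.15]) * peak, lb[:3], ub[:3])
        try:
            sol = least_squares(resid, np.concatenate([A0, lam0]), bounds=(lb, ub))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise BloodFitError("tri-exponential fit did not converge", residuals=None)
    A, lam = best.x[:3], best.x[3:]
    # bounded-residual check: fitted curve should track the data
    scale = max(peak, 1e-12)
    rel = np.abs(resid(best.x)) / scale
    if np.median(rel) > 0.5:
        raise BloodFitError(
            "tri-exponential fit residuals exceed half the peak value",
            residuals=resid(best.x),
        )
    order = np.argsort(-lam)  # fastest component first, cosmetic
    A, lam = A[order], np.maximum(lam[order], 1e-5)
    pre_t = t[: ipk + 1].copy()
    pre_v = y[: ipk + 1].copy()
    pre_v[-1] = float(A.sum())  # continuity at the peak (diagnostic: peak - sum(A))
    model = InputFunction(pre_t, pre_v, A, lam)
    return model
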