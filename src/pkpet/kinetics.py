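"""Two-tissue compartment model (2TCM) forward kinetics.

The reversible two-tissue model with plasma input C_p has impulse response

    h(t) = K1 * [ B1 * exp(-alpha1 t) + B2 * exp(-alpha2 t) ],

    alpha_{1,2} = ( (k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4) ) / 2,
    B1 = (k3 + k4 - alpha1) / (alpha2 - alpha1),
    B2 = (alpha2 - k3 - k4) / (alpha2 - alpha1),

and the tissue concentration is C_t(t) = (h * C_p)(t). Because C_p is
piecewise linear before its peak and tri-exponential after it, the
convolution is evaluated in closed form. Measured voxel/region signal adds
a fractional blood volume: (1 - vB) C_t + vB C_p, averaged over each
acquisition frame.

The total distribution volume of the model is
V_T = (K1/k2) (1 + k3/k4), the equilibrium tissue-to-plasma ratio.

All simulated activities are decay-corrected to injection time, so the
radionuclide half-life does not enter the kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import FrameSchedule
from .input_function import InputFunction
from .tac import TimeActivityCurve

__all__ = [
    "TissueKineticParams",
    "analytic_vt",
    "tissue_concentration",
    "simulate_2tcm",
    "frame_average",
]


class UndefinedVTError(ValueError):
    """V_T is undefined for the given rate constants (k2 or k4 zero)."""


@dataclass(frozen=True)
class TissueKineticParams:
    """Rate constants of the two-tissue compartment model.

    K1 in mL.cm^-3.min^-1; k2, k3, k4 in 1/min; vB the unitless fractional
    blood volume in [0, 0.2]. A one-tissue model is the special case
    k3 = k4 = 0.
    """

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    vB: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.K1, self.k2, self.k3, self.k4, self.vB)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("kinetic parameters must be finite")
        if self.K1 < 0 or self.k3 < 0 or self.k4 < 0:
            raise ValueError("rate constants must be non-negative")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if self.k3 > 0 and self.k4 <= 0:
            raise ValueError("k4 must be positive when k3 > 0 (reversible binding)")
        if not 0.0 <= self.vB <= 0.2:
            raise ValueError("vB must lie in [0, 0.2]")


def analytic_vt(params: TissueKineticParams) -> float:
    """Total distribution volume V_T = (K1/k2)(1 + k3/k4)."""
    if params.k2 <= 0:
        raise UndefinedVTError("V_T undefined for k2 = 0")
    if params.k3 > 0:
        if params.k4 <= 0:
            raise UndefinedVTError("V_T undefined for k3 > 0 with k4 = 0")
        return params.K1 / params.k2 * (1.0 + params.k3 / params.k4)
    return params.K1 / params.k2


def _exp_conv(alpha: float, input_fn: InputFunction, t: np.ndarray) -> np.ndarray:
    """Closed-form F(t) = int_0^t exp(-alpha (t - s)) C_p(s) ds.

    Exact for the piecewise-linear + tri-exponential input representation.
    """
    t = np.asarray(t, dtype=float)
    nt, nv = input_fn.prepeak_times, input_fn.prepeak_values
    tp = input_fn.t_peak
    out = np.zeros_like(t)

    # linear segments [a, b] with value va + m (s - a)
    a = nt[:-1][None, :]
    b = nt[1:][None, :]
    va = nv[:-1][None, :]
    m = (np.diff(nv) / np.diff(nt))[None, :]
    tt = t[:, None]
    tau = np.minimum(tt, b)  # integration upper limit within the segment
    active = tt > a
    d = np.where(active, tau - a, 0.0)  # length integrated within segment
    e_end = np.exp(-alpha * np.maximum(tt - tau, 0.0))
    e_start = np.exp(-alpha * np.maximum(tt - a, 0.0))
    if alpha > 1e-12:
        base = (e_end - e_start) / alpha
        seg = va * base + m * (d * e_end - base) / alpha
    else:
        seg = va * d + 0.5 * m * d**2
    out += np.sum(np.where(active, seg, 0.0), axis=1)

    # tri-exponential tail beyond the peak
    post = t > tp
    if np.any(post):
        u = (t[post] - tp)[:, None]
        A = input_fn.amplitudes[None, :]
        lam = input_fn.rates[None, :]
        denom = alpha - lam
        near = np.abs(denom) < 1e-10
        safe = np.where(near, 1.0, denom)
        tail = A * (np.exp(-lam * u) - np.exp(-alpha * u)) / safe
        tail = np.where(near, A * u * np.exp(-alpha * u), tail)
        out[post] += tail.sum(axis=1)

    return out * input_fn.parent_fraction


def tissue_concentration(
    params: TissueKineticParams, input_fn: InputFunction, t: np.ndarray
) -> np.ndarray:
    """Instantaneous tissue concentration C_t(t) (no blood-volume term)."""
    t = np.asarray(t, dtype=float)
    if params.K1 == 0.0:
        return np.zeros_like(t)
    k2, k3, k4 = params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    if disc < 0:  # numerically impossible for valid rates; guard round-off
        disc = 0.0
    root = np.sqrt(disc)
    if root < 1e-12 * max(s, 1.0):
        # repeated eigenvalue: nudge k4 to split the roots (relative 1e-9)
        k4 = k4 * (1.0 + 1e-9) + 1e-15
        s = k2 + k3 + k4
        root = np.sqrt(max(s * s - 4.0 * k2 * k4, 1e-30))
    a1 = 0.5 * (s - root)
    a2 = 0.5 * (s + root)
    b1 = (k3 + k4 - a1) / (a2 - a1)
    b2 = (a2 - k3 - k4) / (a2 - a1)
    out = np.zeros_like(t)
    if abs(b1) > 0:
        out += b1 * _exp_conv(a1, input_fn, t)
    if abs(b2) > 0:
        out += b2 * _exp_conv(a2, input_fn, t)
    return params.K1 * out


def _frame_grids(schedule: FrameSchedule, nodes_min: np.ndarray, pts_per_min: float = 30.0):
    """Per-frame quadrature grids (minutes), split at input-curve nodes."""
    grids = []
    t0 = schedule.frame_start / 60.0
    t1 = schedule.frame_end / 60.0
    for a, b in zip(t0, t1):
        n = max(9, int(np.ceil((b - a) * pts_per_min)) + 1)
        g = np.linspace(a, b, n)
        inner = nodes_min[(nodes_min > a) & (nodes_min < b)]
        if inner.size:
            g = np.union1d(g, inner)
        grids.append(g)
    return grids


def frame_average(fn, schedule: FrameSchedule, nodes_min=None) -> np.ndarray:
    """Average a callable fn(t_minutes) over each acquisition frame.

    Dense trapezoid quadrature on a per-frame subgrid, with grid points
    inserted at ``nodes_min`` (slope discontinuities of the integrand).
    """
    nodes = np.asarray(nodes_min, dtype=float) if nodes_min is not None else np.empty(0)
    grids = _frame_grids(schedule, nodes)
    allt = np.concatenate(grids)
    vals = np.asarray(fn(allt), dtype=float)
    out = np.empty(len(grids))
    i = 0
    for k, g in enumerate(grids):
        v = vals[i : i + g.size]
        out[k] = np.trapezoid(v, g) / (g[-1] - g[0])
        i += g.size
    return out


def simulate_2tcm(
    params: TissueKineticParams,
    input_fn: InputFunction,
    schedule: FrameSchedule,
) -> TimeActivityCurve:
    """Frame-averaged measured signal of the 2TCM.

    Each frame value is (1/dt) * integral over the frame of
    (1 - vB) C_t(t) + vB C_p(t); the TAC is indexed at frame midpoints.
    """
    if schedule.n_frames == 0:
        raise ValueError("schedule must be non-empty")

    def signal(t):
        ct = tissue_concentration(params, input_fn, t)
        if params.vB > 0:
            return (1.0 - params.vB) * ct + params.vB * input_fn(t)
        return ct

    values = frame_average(signal, schedule, nodes_min=input_fn.node_times())
    return TimeActivityCurve(schedule.mid_times_min, values, unit="kBq/mL")
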