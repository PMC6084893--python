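"""Supervised-cluster reference-region extraction (SuperPK-style).

Each brain voxel's TAC is normalized to unit area and decomposed by
non-negative least squares against four normalized kinetic class curves
(reference gray matter, white matter, high-binding tissue, blood). Voxels
whose reference-gray coefficient exceeds a threshold form the pseudo
reference region; the reference TAC is their coefficient-weighted mean raw
TAC. When too few voxels qualify (e.g., widespread activation) extraction
reports status ``failed`` rather than raising, so pipelines can drop the
subject and continue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .phantom import DynamicImage, PhantomSpec, region_tacs
from .tac import TimeActivityCurve
from .voi import EmptyMaskError, RegionMask

__all__ = [
    "KineticClassLibrary",
    "ReferenceExtractionResult",
    "normalize_curve",
    "decompose_voxel",
    "extract_reference_curve",
    "library_from_phantom",
    "nnls_fixed_design",
]

DEFAULT_CLASS_NAMES = ("reference_gray", "white", "high_binding", "blood")


def _trapezoid_weights(t: np.ndarray) -> np.ndarray:
    """Quadrature weights w such that w @ y = trapezoid integral of y over t."""
    w = np.zeros_like(t)
    dt = np.diff(t)
    w[:-1] += 0.5 * dt
    w[1:] += 0.5 * dt
    return w


def normalize_curve(tac: TimeActivityCurve) -> TimeActivityCurve:
    """Divide a non-negative curve by its trapezoidal area (output area = 1)."""
    if np.any(tac.values < 0):
        raise ValueError("curve must be non-negative")
    area = float(_trapezoid_weights(tac.mid_times) @ tac.values)
    if area <= 0:
        raise ValueError("curve has zero area; cannot normalize")
    return TimeActivityCurve(tac.mid_times, tac.values / area, unit=tac.unit)


@dataclass(frozen=True)
class KineticClassLibrary:
    """Normalized mean curves of the kinetic classes on a common time grid."""

    times: np.ndarray  # minutes
    curves: np.ndarray  # (n_classes, n_times), each unit trapezoidal area
    class_names: Tuple[str, ...] = DEFAULT_CLASS_NAMES
    reference_class: str = "reference_gray"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.curves, dtype=float)
        if c.shape != (len(self.class_names), t.size):
            raise ValueError("curves must be (n_classes, n_times)")
        if len(self.class_names) != len(set(self.class_names)):
            raise ValueError("class names must be unique")
        if self.reference_class not in self.class_names:
            raise ValueError("reference_class must be one of class_names")
        if np.any(c < 0):
            raise ValueError("class curves must be non-negative")
        w = _trapezoid_weights(t)
        areas = c @ w
        if not np.allclose(areas, 1.0, rtol=1e-6):
            raise ValueError("class curves must have unit trapezoidal area")
        # pairwise distinctness
        for i in range(c.shape[0]):
            for j in range(i + 1, c.shape[0]):
                if np.allclose(c[i], c[j], rtol=1e-8, atol=1e-12):
                    raise ValueError(
                        f"classes '{self.class_names[i]}' and "
                        f"'{self.class_names[j]}' are identical"
                    )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "curves", c)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def reference_index(self) -> int:
        return self.class_names.index(self.reference_class)


def library_from_phantom(
    spec: PhantomSpec,
    class_map: Optional[Dict[str, str]] = None,
) -> KineticClassLibrary:
    """Build the class library from a phantom's own kinetic definitions.

    By default reference_gray <- 'cgm', white <- 'wm', high_binding <- 'th',
    blood <- 'carotid'. For real-data use a library can instead be loaded
    from file (see :mod:`pkpet.io`).
    """
    class_map = class_map or {
        "reference_gray": "cgm",
        "white": "wm",
        "high_binding": "th",
        "blood": "carotid",
    }
    tacs = region_tacs(spec)
    times = spec.schedule.mid_times_min
    curves = np.stack(
        [normalize_curve(tacs[class_map[name]]).values for name in DEFAULT_CLASS_NAMES]
    )
    return KineticClassLibrary(times, curves, DEFAULT_CLASS_NAMES)


def nnls_fixed_design(A: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Non-negative least squares with one design matrix and many targets.

    Solves min ||A c - y||_2 s.t. c >= 0 for every row y of ``Y`` by
    enumerating the active sets of the (small) design: for each nonempty
    support S, the unconstrained least-squares solution restricted to S is
    computed with a precomputed pseudo-inverse; among the feasible
    candidates (c >= 0, zeros elsewhere) the one with the smallest residual
    is the NNLS solution (its support satisfies the stationarity condition
    by construction).

    A: (n_times, k) with k small (4 classes); Y: (n_targets, n_times).
    Returns coefficients of shape (n_targets, k).
    """
    n, k = A.shape
    if k > 10:
        raise ValueError("active-set enumeration is for small designs only")
    m = Y.shape[0]
    best_res = np.full(m, np.inf)
    best_c = np.zeros((m, k))
    yy = np.einsum("ij,ij->i", Y, Y)
    for mask in range(1, 2**k):
        idx = [i for i in range(k) if mask >> i & 1]
        As = A[:, idx]
        pinv = np.linalg.pinv(As)
        cs = Y @ pinv.T  # (m, |S|)
        feasible = np.all(cs >= 0, axis=1)
        if not feasible.any():
            continue
        fit = cs @ As.T
        res = yy - 2 * np.einsum("ij,ij->i", fit, Y) + np.einsum("ij,ij->i", fit, fit)
        better = feasible & (res < best_res)
        if better.any():
            best_res[better] = res[better]
            c_full = np.zeros((int(better.sum()), k))
            c_full[:, idx] = cs[better]
            best_c[better] = c_full
    return best_c


def decompose_voxel(
    voxel_tac: TimeActivityCurve, library: KineticClassLibrary
) -> np.ndarray:
    """NNLS coefficients of a voxel curve against the class library.

    The voxel curve is area-normalized, decomposed against the normalized
    class curves, and the coefficients rescaled to sum to 1 (an all-zero
    solution is returned unscaled).
    """
    if not np.all(np.isfinite(voxel_tac.values)):
        raise ValueError("voxel TAC contains non-finite values")
    if not np.allclose(voxel_tac.mid_times, library.times):
        raise ValueError("voxel TAC must be on the library time grid")
    coefs = decompose_curves(voxel_tac.values[None, :], library)[0]
    return coefs


def decompose_curves(values: np.ndarray, library: KineticClassLibrary) -> np.ndarray:
    """Vectorized :func:`decompose_voxel` over rows of ``values``."""
    w = _trapezoid_weights(library.times)
    areas = values @ w
    ok = areas > 0
    norm = np.zeros_like(values)
    norm[ok] = values[ok] / areas[ok, None]
    coefs = np.zeros((values.shape[0], library.n_classes))
    if ok.any():
        coefs[ok] = nnls_fixed_design(library.curves.T, norm[ok])
    sums = coefs.sum(axis=1)
    nz = sums > 0
    coefs[nz] /= sums[nz, None]
    return coefs


@dataclass(frozen=True)
class ReferenceExtractionResult:
    """Outcome of supervised-cluster reference extraction.

    status is "ok" or "failed"; on failure no TAC is returned. The
    coefficient map holds the reference-class coefficient of every
    brain-mask voxel (zeros outside the mask).
    """

    status: str
    tac: Optional[TimeActivityCurve]
    coefficient_map: np.ndarray
    selected_voxel_count: int
    selected_fraction: float
    weight_mass: float


def extract_reference_curve(
    img: DynamicImage,
    brain_mask: RegionMask,
    library: KineticClassLibrary,
    coef_threshold: float = 0.9,
    min_voxel_fraction: float = 0.01,
    classify_smooth_fwhm_mm: float = 4.0,
) -> ReferenceExtractionResult:
    """Extract a pseudo-reference TAC from a dynamic image.

    Voxels in ``brain_mask`` with reference-class coefficient >=
    ``coef_threshold`` are averaged (weighted by their coefficients). If
    fewer than ``min_voxel_fraction`` of mask voxels qualify, status is
    "failed" and no TAC is returned — a status, not an exception, so a
    multi-subject pipeline can drop the subject and continue.

    Classification (not the extracted TAC) runs on a copy of the image
    lightly smoothed by ``classify_smooth_fwhm_mm``: single-voxel TACs are
    far too noisy for reliable shape decomposition, while the reference TAC
    itself averages the raw voxel curves so no extra partial-volume bias is
    introduced. Set to 0 to classify on raw voxels.
    """
    if brain_mask.is_empty():
        raise EmptyMaskError("brain mask is empty")
    if img.data.shape[:3] != brain_mask.data.shape:
        raise ValueError("image and mask grids differ")
    if not np.allclose(img.schedule.mid_times_min, library.times):
        raise ValueError("library time grid does not match the image schedule")
    vox = img.data[brain_mask.data]  # (n_vox, n_frames)
    if classify_smooth_fwhm_mm > 0:
        from scipy.ndimage import gaussian_filter

        from .phantom import FWHM_TO_SIGMA

        sigma = [
            classify_smooth_fwhm_mm * FWHM_TO_SIGMA / v for v in img.voxel_size_mm
        ]
        smooth = np.empty_like(img.data)
        for k in range(img.data.shape[3]):
            smooth[..., k] = gaussian_filter(img.data[..., k], sigma=sigma, mode="constant")
        class_vox = smooth[brain_mask.data]
    else:
        class_vox = vox
    coefs = decompose_curves(np.maximum(class_vox, 0.0), library)
    ref_coef = coefs[:, library.reference_index]
    coef_map = np.zeros(brain_mask.data.shape)
    coef_map[brain_mask.data] = ref_coef
    selected = ref_coef >= coef_threshold
    n_sel = int(selected.sum())
    frac = n_sel / vox.shape[0]
    weight_mass = float(ref_coef[selected].sum())
    if frac < min_voxel_fraction or weight_mass <= 0:
        return ReferenceExtractionResult(
            status="failed",
            tac=None,
            coefficient_map=coef_map,
            selected_voxel_count=n_sel,
            selected_fraction=frac,
            weight_mass=weight_mass,
        )
    weights = ref_coef[selected]
    ref_values = weights @ vox[selected] / weights.sum()
    tac = TimeActivityCurve(img.schedule.mid_times_min, ref_values, unit=img.unit)
    return ReferenceExtractionResult(
        status="ok",
        tac=tac,
        coefficient_map=coef_map,
        selected_voxel_count=n_sel,
        selected_fraction=frac,
        weight_mass=weight_mass,
    )
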