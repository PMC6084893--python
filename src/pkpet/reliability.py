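"""Test-retest reliability metrics and the phantom comparison experiment.

Signed test-retest variability as a percent of the pair mean:

    TRV = 100 * (T - RT) / ((T + RT) / 2)

aTRV is the mean of |TRV|. The repeatability coefficient, the bound below
which ~95% of absolute test-retest differences fall, is 2.77 times the
within-subject coefficient of variation with the paired-difference
variance estimator:

    %RC = 100 * 2.77 * sqrt( (1/P) * sum_j [ (T_j - RT_j)^2 / 2 ]
                                        / [ (T_j + RT_j) / 2 ]^2 )

which reduces to 2.77 * CV for a single pair.

``run_trt_experiment`` runs the full phantom comparison: for each simulated
subject it generates a test-retest pair, extracts the image-derived input
function and the supervised-cluster reference curve, fits blood-input
Logan V_T and reference-Logan BP_ND on a VOI erosion series and on every
lesion, and summarizes TRV/aTRV/%RC per region and method. Subjects whose
reference extraction fails are excluded from the BP_ND summaries (and
logged) without affecting the V_T arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .input_function import BloodFitError, fit_blood_model
from .logan import LoganConfig, logan_vt, reference_logan_bpnd
from .phantom import (
    DynamicImage,
    LabelMap,
    PhantomSpec,
    build_label_map,
    make_test_retest_pair,
    render_noiseless,
)
from .reference import KineticClassLibrary, extract_reference_curve, library_from_phantom
from .tac import TimeActivityCurve, auc
from .voi import RegionMask, erode_mask, erosion_series, extract_idif, extract_tac

__all__ = [
    "trv",
    "summarize_trv",
    "percent_rc",
    "auc_ratio_report",
    "paired_ttest",
    "TestRetestPair",
    "ReliabilitySummary",
    "ExperimentResult",
    "phantom_masks",
    "run_trt_experiment",
    "AUC_INTERVALS_MIN",
]

#: The three AUC comparison intervals, in minutes.
AUC_INTERVALS_MIN = ((20.0, 60.0), (40.0, 60.0), (1.0, 60.0))


def trv(T: float, RT: float) -> float:
    """Signed test-retest variability in percent of the pair mean."""
    mean = 0.5 * (T + RT)
    if mean == 0:
        raise ZeroDivisionError("pair mean is zero; TRV undefined")
    return 100.0 * (T - RT) / mean


@dataclass(frozen=True)
class TestRetestPair:
    """One region's test and retest estimates for one subject and method."""

    subject: int
    region: str
    method: str  # "LGM_VT" or "RLGM_BPND"
    T: float
    RT: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.T) and np.isfinite(self.RT)):
            raise ValueError("T and RT must be finite")


def summarize_trv(pairs: Sequence) -> Tuple[float, float, float, float]:
    """(mean TRV, SD TRV, mean aTRV, SD aTRV) over pairs.

    Accepts :class:`TestRetestPair` objects or (T, RT) tuples. SDs use the
    P-1 denominator (NaN for a single pair).
    """
    if len(pairs) == 0:
        raise ValueError("at least one pair is required")
    vals = np.array([trv(p.T, p.RT) if hasattr(p, "T") else trv(*p) for p in pairs])
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
    asd = float(np.std(np.abs(vals), ddof=1)) if vals.size > 1 else float("nan")
    return float(vals.mean()), sd, float(np.abs(vals).mean()), asd


def percent_rc(pairs: Sequence) -> float:
    """Repeatability coefficient in percent (2.77 x within-subject CV)."""
    if len(pairs) == 0:
        raise ValueError("at least one pair is required")
    tr = np.array([(p.T, p.RT) if hasattr(p, "T") else tuple(p) for p in pairs], dtype=float)
    means = 0.5 * tr.sum(axis=1)
    if np.any(means == 0):
        raise ZeroDivisionError("a pair mean is zero; %RC undefined")
    cv2 = np.mean((np.diff(tr, axis=1)[:, 0] ** 2 / 2.0) / means**2)
    return 100.0 * 2.77 * float(np.sqrt(cv2))


def auc_ratio_report(
    test_if: TimeActivityCurve, retest_if: TimeActivityCurve
) -> Dict[str, float]:
    """Test/retest AUC ratios over the 20-60, 40-60 and 1-60 min intervals."""
    out = {}
    for t0, t1 in AUC_INTERVALS_MIN:
        denom = auc(retest_if, t0, t1)
        if denom == 0:
            raise ZeroDivisionError(f"retest AUC over [{t0}, {t1}] min is zero")
        out[f"{t0:g}-{t1:g}"] = auc(test_if, t0, t1) / denom
    return out


def paired_ttest(test_values: Sequence[float], retest_values: Sequence[float]):
    """Two-tailed paired t-test (convenience wrapper, standard statistics)."""
    return stats.ttest_rel(np.asarray(test_values), np.asarray(retest_values))


@dataclass(frozen=True)
class ReliabilitySummary:
    """Per-region, per-method TRV/aTRV/%RC statistics."""

    region: str
    method: str
    n_pairs: int
    mean_trv: float
    sd_trv: float
    mean_atrv: float
    sd_atrv: float
    rc_percent: float


# ---------------------------------------------------------------------------
# experiment harness


def phantom_masks(
    spec: PhantomSpec,
    labels: Optional[LabelMap] = None,
    brain_mask_erosion: int = 5,
    min_volume_cm3: float = 1.0,
) -> Dict[str, object]:
    """Build the analysis masks of a phantom.

    Returns a dict with the named VOIs ('TH', 'TH-1', ..., 'WM', 'WM-1',
    ..., 'CGM' — the base region plus its erosion series), per-lesion masks
    (rim plus core), the carotid mask, a background-ROI mask ~2 cm from the
    carotids (IDIF spill-in diagnostic), and the eroded brain mask used for
    reference extraction (edge voxels are partial-volume diluted, so the
    brain mask is eroded by ``brain_mask_erosion`` voxels).
    """
    labels = labels or build_label_map(spec)
    vx = spec.voxel_size_mm

    def rm(data, name):
        return RegionMask(data, vx, name)

    vois: Dict[str, RegionMask] = {}
    for base, key in (("TH", "th"), ("WM", "wm")):
        series = erosion_series(rm(labels.mask(key), base), min_volume_cm3)
        vois[base] = series[0]
        for i, m in enumerate(series[1:], start=1):
            vois[f"{base}-{i}"] = m
    vois["CGM"] = rm(labels.mask("cgm"), "CGM")

    lesions: Dict[str, RegionMask] = {}
    j = 0
    while f"lesion_rim_{j}" in labels.ids:
        data = labels.mask(f"lesion_rim_{j}") | labels.mask(f"lesion_core_{j}")
        lesions[f"lesion_{j}"] = rm(data, f"lesion_{j}")
        j += 1

    carotid = rm(labels.mask("carotid"), "carotid")
    background = _idif_background_mask(spec, labels)
    brain_data = np.zeros(spec.shape, dtype=bool)
    for name, lid in labels.ids.items():
        if name not in ("background", "carotid"):
            brain_data |= labels.data == lid
    brain = rm(brain_data, "brain")
    if brain_mask_erosion > 0:
        brain = erode_mask(brain, brain_mask_erosion)
    return {
        "vois": vois,
        "lesions": lesions,
        "carotid": carotid,
        "background": background,
        "brain": brain,
    }


def _idif_background_mask(spec: PhantomSpec, labels: LabelMap) -> RegionMask:
    """8-mm-diameter spherical ROIs ~2 cm lateral to each carotid tube."""
    from .phantom import Ellipsoid, Tube, _voxel_centers_mm

    xyz = _voxel_centers_mm(spec.shape, spec.voxel_size_mm)
    data = np.zeros(spec.shape, dtype=bool)
    for name, geom in spec.regions:
        if name == "carotid" and isinstance(geom, Tube):
            cx, cy = geom.center_xy_mm
            offset = 20.0 if cx >= 0 else -20.0  # ~2 cm lateral
            roi = Ellipsoid((cx + offset, cy, 0.0), (4.0, 4.0, 4.0))
            data |= roi.contains(xyz)
    data &= labels.data == 0  # keep ROIs in background tissue
    return RegionMask(data, spec.voxel_size_mm, "idif_background")


@dataclass
class ExperimentResult:
    """Output of :func:`run_trt_experiment`.

    summary: one row per (region, method) with P, mean/SD TRV, mean/SD
    aTRV and %RC. lesion_pairs: per-lesion, per-method T/RT/TRV rows.
    pairs: every region-level pair. idif_auc: per-subject test/retest AUC
    ratios of the IDIF. excluded_subjects: subjects dropped from the BP_ND
    arm (reference extraction failed). bpnd_error: set when every subject
    failed extraction (the BP_ND arm is then absent).
    """

    summary: pd.DataFrame
    lesion_pairs: pd.DataFrame
    pairs: pd.DataFrame
    idif_auc: pd.DataFrame
    excluded_subjects: List[int]
    bpnd_error: Optional[str]
    manifest: Dict[str, object]


def _summaries(pairs: List[TestRetestPair]) -> pd.DataFrame:
    rows = []
    df = pd.DataFrame([(p.subject, p.region, p.method, p.T, p.RT) for p in pairs],
                      columns=["subject", "region", "method", "T", "RT"])
    for (region, method), grp in df.groupby(["region", "method"], sort=False):
        pr = list(grp[["T", "RT"]].itertuples(index=False, name=None))
        m, sd, am, asd = summarize_trv(pr)
        rows.append(
            {
                "region": region,
                "method": method,
                "P": len(pr),
                "mean_trv_pct": m,
                "sd_trv_pct": sd,
                "mean_atrv_pct": am,
                "sd_atrv_pct": asd,
                "rc_pct": percent_rc(pr),
            }
        )
    return pd.DataFrame(rows)


def run_trt_experiment(
    spec: PhantomSpec,
    n_subjects: int = 10,
    seed: int = 7,
    dose_jitter_fraction: float = 0.15,
    methods: Sequence[str] = ("LGM_VT", "RLGM_BPND"),
    config: Optional[LoganConfig] = None,
    library: Optional[KineticClassLibrary] = None,
    k2_prime: Optional[float] = None,
    brain_mask_erosion: int = 5,
    min_volume_cm3: float = 1.0,
) -> ExperimentResult:
    """Run the full test-retest method-comparison experiment on a phantom.

    Each "subject" is an independent noise realization of the phantom with
    its own dose jitter (geometry and kinetics are shared — anatomical
    variability is out of scope). Both estimators are fitted on the TH and
    WM erosion series, the CGM VOI, and every lesion mask.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    config = config or LoganConfig()
    run_bpnd = "RLGM_BPND" in methods
    run_vt = "LGM_VT" in methods
    if library is None and run_bpnd:
        library = library_from_phantom(spec)

    noiseless = render_noiseless(spec)
    masks = phantom_masks(spec, brain_mask_erosion=brain_mask_erosion,
                          min_volume_cm3=min_volume_cm3)
    all_vois: Dict[str, RegionMask] = dict(masks["vois"])
    lesion_vois: Dict[str, RegionMask] = masks["lesions"]

    master = np.random.default_rng(seed)
    subj_seeds = master.integers(0, 2**31 - 2, size=(n_subjects, 2))

    pairs: List[TestRetestPair] = []
    lesion_rows: List[dict] = []
    auc_rows: List[dict] = []
    excluded: List[int] = []

    for j in range(n_subjects):
        st, sr = int(subj_seeds[j, 0]), int(subj_seeds[j, 1])
        if st == sr:
            sr += 1
        test, retest, _ = make_test_retest_pair(
            spec, st, sr, dose_jitter_fraction, noiseless=noiseless
        )

        estimates: Dict[str, Dict[Tuple[str, str], float]] = {"test": {}, "retest": {}}
        ref_failed = False
        idif_tacs = {}
        for tag, img in (("test", test), ("retest", retest)):
            vt_input = None
            if run_vt:
                idif = extract_idif(img, masks["carotid"], masks["background"])
                idif_tacs[tag] = idif.tac
                vt_input = fit_blood_model(idif.tac)
            ref_tac = None
            if run_bpnd:
                res = extract_reference_curve(img, masks["brain"], library)
                if res.status == "failed":
                    ref_failed = True
                else:
                    ref_tac = res.tac
            for name, mask in {**all_vois, **lesion_vois}.items():
                tac = extract_tac(img, mask)
                if run_vt:
                    estimates[tag][(name, "LGM_VT")] = logan_vt(tac, vt_input, config).vt
                if run_bpnd and ref_tac is not None:
                    estimates[tag][(name, "RLGM_BPND")] = reference_logan_bpnd(
                        tac, ref_tac, config, k2_prime
                    ).bp_nd

        if run_vt:
            ratios = auc_ratio_report(idif_tacs["test"], idif_tacs["retest"])
            auc_rows.append({"subject": j, **{f"auc_{k}": v for k, v in ratios.items()}})
        if ref_failed:
            excluded.append(j)

        for (name, method), T in estimates["test"].items():
            if (name, method) not in estimates["retest"]:
                continue
            RT = estimates["retest"][(name, method)]
            if name in lesion_vois:
                lesion_rows.append(
                    {
                        "subject": j,
                        "lesion": name,
                        "volume_cm3": lesion_vois[name].volume_cm3,
                        "method": method,
                        "T": T,
                        "RT": RT,
                        "trv_pct": trv(T, RT),
                    }
                )
            else:
                pairs.append(TestRetestPair(j, name, method, T, RT))

    bpnd_error = None
    if run_bpnd and len(excluded) == n_subjects:
        bpnd_error = (
            "reference extraction failed for every subject; "
            "the BP_ND arm has no data"
        )

    summary = _summaries(pairs) if pairs else pd.DataFrame(
        columns=["region", "method", "P", "mean_trv_pct", "sd_trv_pct",
                 "mean_atrv_pct", "sd_atrv_pct", "rc_pct"]
    )
    manifest = {
        "seed": int(seed),
        "n_subjects": int(n_subjects),
        "dose_jitter_fraction": float(dose_jitter_fraction),
        "noise_scale": float(spec.noise_scale),
        "t_star_min": float(config.t_star),
        "k2_prime": k2_prime,
        "subject_seeds": subj_seeds.tolist(),
        "excluded_subjects": excluded,
    }
    return ExperimentResult(
        summary=summary,
        lesion_pairs=pd.DataFrame(lesion_rows),
        pairs=pd.DataFrame([(p.subject, p.region, p.method, p.T, p.RT,
                             trv(p.T, p.RT)) for p in pairs],
                           columns=["subject", "region", "method", "T", "RT", "trv_pct"]),
        idif_auc=pd.DataFrame(auc_rows),
        excluded_subjects=excluded,
        bpnd_error=bpnd_error,
        manifest=manifest,
    )
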