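"""File formats: TAC/schedule/library tables, NIfTI images, phantom configs.

Tabular data are TSV (columns documented per function). Images are NIfTI-1
via nibabel, with timing or label tables as sidecar files. Phantom specs are
versioned YAML so a simulation is fully reproducible from its config file.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Tuple, Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .frames import FrameSchedule
from .input_function import InputFunction
from .kinetics import TissueKineticParams
from .logan import LoganResults
from .phantom import (
    BLOOD_POOL,
    Box,
    DynamicImage,
    Ellipsoid,
    LabelMap,
    PhantomSpec,
    Shell,
    Tube,
)
from .reference import DEFAULT_CLASS_NAMES, KineticClassLibrary
from .tac import TimeActivityCurve

__all__ = [
    "read_tac",
    "write_tac",
    "read_schedule",
    "write_schedule",
    "read_dynamic_image",
    "write_dynamic_image",
    "read_label_map",
    "write_label_map",
    "read_class_library",
    "write_class_library",
    "read_phantom_spec",
    "write_phantom_spec",
    "write_logan_results",
]

SPEC_FORMAT_VERSION = 1


# ---------------------------------------------------------------- TAC tables
def write_tac(tac: TimeActivityCurve, path: Union[str, Path]) -> None:
    """TSV with columns mid_time_min, value, unit."""
    df = pd.DataFrame(
        {"mid_time_min": tac.mid_times, "value": tac.values, "unit": tac.unit}
    )
    df.to_csv(path, sep="\t", index=False)


def read_tac(path: Union[str, Path]) -> TimeActivityCurve:
    df = pd.read_csv(path, sep="\t")
    for col in ("mid_time_min", "value"):
        if col not in df.columns:
            raise ValueError(f"TAC table missing column '{col}'")
    unit = str(df["unit"].iloc[0]) if "unit" in df.columns else "kBq/mL"
    return TimeActivityCurve(
        df["mid_time_min"].to_numpy(float), df["value"].to_numpy(float), unit=unit
    )


# ------------------------------------------------------------ frame schedules
def write_schedule(schedule: FrameSchedule, path: Union[str, Path]) -> None:
    """TSV with columns frame_start_s, frame_duration_s."""
    df = pd.DataFrame(
        {
            "frame_start_s": schedule.frame_start,
            "frame_duration_s": schedule.frame_duration,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_schedule(path: Union[str, Path]) -> FrameSchedule:
    df = pd.read_csv(path, sep="\t")
    for col in ("frame_start_s", "frame_duration_s"):
        if col not in df.columns:
            raise ValueError(f"schedule table missing column '{col}'")
    return FrameSchedule(
        df["frame_start_s"].to_numpy(float), df["frame_duration_s"].to_numpy(float)
    )


# ------------------------------------------------------------------- images
def _affine(voxel_size_mm: Tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def write_dynamic_image(img: DynamicImage, path: Union[str, Path]) -> None:
    """NIfTI-1 4D image plus a frame-timing TSV sidecar (same stem)."""
    path = Path(path)
    nii = nib.Nifti1Image(img.data.astype(np.float32), _affine(img.voxel_size_mm))
    nii.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(nii, str(path))
    write_schedule(img.schedule, _sidecar(path, "_frames.tsv"))


def read_dynamic_image(path: Union[str, Path]) -> DynamicImage:
    path = Path(path)
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj, dtype=float)
    voxel = tuple(float(z) for z in nii.header.get_zooms()[:3])
    schedule = read_schedule(_sidecar(path, "_frames.tsv"))
    return DynamicImage(data, voxel, schedule)


def _sidecar(path: Path, suffix: str) -> Path:
    stem = path.name
    for ext in (".nii.gz", ".nii"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
            break
    return path.with_name(stem + suffix)


def write_label_map(labels: LabelMap, path: Union[str, Path]) -> None:
    """Integer NIfTI-1 plus a JSON sidecar mapping label names to ids."""
    path = Path(path)
    nii = nib.Nifti1Image(
        labels.data.astype(np.int16), _affine(labels.voxel_size_mm)
    )
    nib.save(nii, str(path))
    _sidecar(path, "_labels.json").write_text(json.dumps(labels.ids, indent=1))


def read_label_map(path: Union[str, Path]) -> LabelMap:
    path = Path(path)
    nii = nib.load(str(path))
    ids = json.loads(_sidecar(path, "_labels.json").read_text())
    voxel = tuple(float(z) for z in nii.header.get_zooms()[:3])
    return LabelMap(np.asarray(nii.dataobj, dtype=np.int16), voxel, dict(ids))


# ------------------------------------------------------------- class library
def write_class_library(
    library: KineticClassLibrary, path: Union[str, Path]
) -> None:
    """TSV: time_min column plus one column per kinetic class."""
    df = pd.DataFrame({"time_min": library.times})
    for name, curve in zip(library.class_names, library.curves):
        df[name] = curve
    df.to_csv(path, sep="\t", index=False)


def read_class_library(
    path: Union[str, Path], reference_class: str = "reference_gray"
) -> KineticClassLibrary:
    df = pd.read_csv(path, sep="\t")
    if "time_min" not in df.columns:
        raise ValueError("class library missing column 'time_min'")
    names = tuple(c for c in df.columns if c != "time_min")
    curves = np.stack([df[c].to_numpy(float) for c in names])
    return KineticClassLibrary(
        df["time_min"].to_numpy(float),
        curves,
        class_names=names,
        reference_class=reference_class,
    )


# -------------------------------------------------------------- phantom spec
_GEOMETRY_TYPES = {"ellipsoid": Ellipsoid, "box": Box, "tube": Tube, "shell": Shell}


def _geometry_to_dict(geom) -> dict:
    for name, cls in _GEOMETRY_TYPES.items():
        if isinstance(geom, cls):
            d = asdict(geom)
            d["type"] = name
            return _plain(d)
    raise TypeError(f"unknown geometry type: {type(geom).__name__}")


def _geometry_from_dict(d: dict):
    d = dict(d)
    cls = _GEOMETRY_TYPES[d.pop("type")]
    for key, val in d.items():
        if isinstance(val, list):
            d[key] = tuple(val)
    return cls(**d)


def _plain(obj):
    """Recursively convert numpy scalars/arrays and tuples to YAML-safe types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_phantom_spec(spec: PhantomSpec, path: Union[str, Path]) -> None:
    """Versioned YAML config; :func:`read_phantom_spec` round-trips it."""
    kin: Dict[str, object] = {}
    for name, params in spec.kinetics.items():
        kin[name] = params if isinstance(params, str) else _plain(asdict(params))
    doc = {
        "format_version": SPEC_FORMAT_VERSION,
        "shape": list(spec.shape),
        "voxel_size_mm": list(spec.voxel_size_mm),
        "regions": [
            {"label": name, "geometry": _geometry_to_dict(geom)}
            for name, geom in spec.regions
        ],
        "kinetics": kin,
        "input_function": {
            "prepeak_times": _plain(spec.input_function.prepeak_times),
            "prepeak_values": _plain(spec.input_function.prepeak_values),
            "amplitudes": _plain(spec.input_function.amplitudes),
            "rates": _plain(spec.input_function.rates),
            "parent_fraction": float(spec.input_function.parent_fraction),
        },
        "schedule": {
            "frame_start_s": _plain(spec.schedule.frame_start),
            "frame_duration_s": _plain(spec.schedule.frame_duration),
        },
        "psf_fwhm_mm": list(spec.psf_fwhm_mm),
        "noise_scale": float(spec.noise_scale),
        "injected_dose_MBq": float(spec.injected_dose_MBq),
        "body_weight_kg": float(spec.body_weight_kg),
        "seed": int(spec.seed),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_phantom_spec(path: Union[str, Path]) -> PhantomSpec:
    doc = yaml.safe_load(Path(path).read_text())
    version = doc.get("format_version")
    if version != SPEC_FORMAT_VERSION:
        raise ValueError(
            f"unsupported phantom config version {version!r} "
            f"(expected {SPEC_FORMAT_VERSION})"
        )
    kinetics: Dict[str, Union[TissueKineticParams, str]] = {}
    for name, params in doc["kinetics"].items():
        if isinstance(params, str):
            if params != BLOOD_POOL:
                raise ValueError(f"unknown kinetics sentinel {params!r}")
            kinetics[name] = BLOOD_POOL
        else:
            kinetics[name] = TissueKineticParams(**params)
    inp = doc["input_function"]
    sched = doc["schedule"]
    return PhantomSpec(
        shape=tuple(doc["shape"]),
        voxel_size_mm=tuple(doc["voxel_size_mm"]),
        regions=tuple(
            (r["label"], _geometry_from_dict(r["geometry"])) for r in doc["regions"]
        ),
        kinetics=kinetics,
        input_function=InputFunction(
            prepeak_times=np.asarray(inp["prepeak_times"], float),
            prepeak_values=np.asarray(inp["prepeak_values"], float),
            amplitudes=tuple(inp["amplitudes"]),
            rates=tuple(inp["rates"]),
            parent_fraction=float(inp["parent_fraction"]),
        ),
        schedule=FrameSchedule(
            np.asarray(sched["frame_start_s"], float),
            np.asarray(sched["frame_duration_s"], float),
        ),
        psf_fwhm_mm=tuple(doc["psf_fwhm_mm"]),
        noise_scale=float(doc["noise_scale"]),
        injected_dose_MBq=float(doc["injected_dose_MBq"]),
        body_weight_kg=float(doc["body_weight_kg"]),
        seed=int(doc["seed"]),
    )


# ------------------------------------------------------------------- results
def write_logan_results(results: LoganResults, path: Union[str, Path]) -> None:
    """One-row TSV: slope, intercept, their SEs, n, r², kind, t_star."""
    df = pd.DataFrame(
        [
            {
                "kind": results.kind,
                "slope": results.slope,
                "intercept": results.intercept,
                "slope_se": results.slope_se,
                "intercept_se": results.intercept_se,
                "n_points": results.n_points,
                "r_squared": results.r_squared,
                "t_star_min": results.t_star,
            }
        ]
    )
    df.to_csv(path, sep="\t", index=False)
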