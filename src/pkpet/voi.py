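"""Volume-of-interest handling: masks, erosion series, TAC/IDIF extraction.

The erosion series emulates moving a VOI boundary toward the region center
in steps of one voxel (anisotropic voxels erode in voxel units, not mm)
until the VOI reaches a minimum volume, to probe partial-volume effects as
a function of region size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure

from .phantom import DynamicImage
from .tac import TimeActivityCurve

__all__ = [
    "RegionMask",
    "EmptyMaskError",
    "erode_mask",
    "erosion_series",
    "extract_tac",
    "extract_idif",
    "IdifResult",
]


class EmptyMaskError(ValueError):
    """A mask operation produced or received an empty mask."""


@dataclass(frozen=True)
class RegionMask:
    """Binary 3D mask with voxel geometry and a label name."""

    data: np.ndarray
    voxel_size_mm: Tuple[float, float, float]
    label: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=bool)
        if d.ndim != 3:
            raise ValueError("mask must be 3-D")
        object.__setattr__(self, "data", d)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return self.voxel_count == 0


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return generate_binary_structure(3, 1)
    if connectivity == 26:
        return generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def erode_mask(mask: RegionMask, steps: int = 1, connectivity: int = 6) -> RegionMask:
    """Morphological erosion by ``steps`` one-voxel shells.

    Uses a face-neighbor (6-connected) structuring element by default.
    Raises :class:`EmptyMaskError` if the result is empty.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    out = binary_erosion(mask.data, structure=_structure(connectivity), iterations=steps)
    if not out.any():
        raise EmptyMaskError(f"erosion by {steps} step(s) emptied mask '{mask.label}'")
    return replace(mask, data=out)


def erosion_series(
    mask: RegionMask, min_volume_cm3: float = 1.0, connectivity: int = 6
) -> List[RegionMask]:
    """Successive one-voxel erosions, largest first.

    The list starts with the input mask and stops before any mask whose
    volume would fall below ``min_volume_cm3``. Volumes are strictly
    decreasing. The input must exceed the minimum volume.
    """
    if mask.volume_cm3 < min_volume_cm3:
        raise ValueError(
            f"mask volume {mask.volume_cm3:.2f} cm^3 is below the "
            f"{min_volume_cm3:.2f} cm^3 minimum"
        )
    series = [mask]
    current = mask
    while True:
        try:
            nxt = erode_mask(current, 1, connectivity=connectivity)
        except EmptyMaskError:
            break
        if nxt.volume_cm3 < min_volume_cm3:
            break
        series.append(nxt)
        current = nxt
    return series


def extract_tac(img: DynamicImage, mask: RegionMask) -> TimeActivityCurve:
    """Per-frame arithmetic mean over the masked voxels."""
    if mask.is_empty():
        raise EmptyMaskError(f"mask '{mask.label}' is empty")
    if img.data.shape[:3] != mask.data.shape:
        raise ValueError("image and mask grids differ")
    values = img.data[mask.data].mean(axis=0)
    return TimeActivityCurve(img.schedule.mid_times_min, values, unit=img.unit)


@dataclass(frozen=True)
class IdifResult:
    """Image-derived input function with its background diagnostic."""

    tac: TimeActivityCurve
    background: TimeActivityCurve
    spill_fraction: float = 0.0


def extract_idif(
    img: DynamicImage,
    carotid_mask: RegionMask,
    background_mask: RegionMask,
    spill_fraction: float = 0.0,
) -> IdifResult:
    """Image-derived input function from carotid-artery ROIs.

    Returns the carotid-mask mean TAC with the background-ROI TAC attached
    as a spill-in diagnostic. With ``spill_fraction`` > 0, that fraction of
    the background TAC is subtracted (default 0: diagnostic only, no
    correction applied).
    """
    carotid = extract_tac(img, carotid_mask)
    background = extract_tac(img, background_mask)
    if spill_fraction != 0.0:
        carotid = replace(carotid, values=carotid.values - spill_fraction * background.values)
    return IdifResult(tac=carotid, background=background, spill_fraction=spill_fraction)
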