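"""Digital dynamic-PET brain phantom.

Builds seeded 4D test-retest acquisitions with the structure the analysis
assumes: a high-binding thalamus-like nucleus, low-binding white matter
surrounded by hotter cortical gray matter, rim-core lesion shells in the
white matter, carotid-artery tubes for image-derived input functions,
stationary Gaussian PSF blurring (partial-volume effect), and
count-dependent Gaussian noise.

Geometry is parametric (ellipsoids, boxes, tubes, shells), not anatomical:
the analyses under test only need realistic sizes, contrasts, and noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .frames import FrameSchedule
from .input_function import InputFunction
from .kinetics import TissueKineticParams, frame_average, simulate_2tcm
from .tac import TimeActivityCurve

__all__ = [
    "Ellipsoid",
    "Box",
    "Tube",
    "Shell",
    "PhantomSpec",
    "DynamicImage",
    "LabelMap",
    "BLOOD_POOL",
    "build_label_map",
    "render_noiseless",
    "add_noise",
    "make_test_retest_pair",
    "default_phantom",
    "widespread_activation_phantom",
    "region_tacs",
]

#: Sentinel kinetics value marking a label as pure blood pool (voxel signal
#: equals the frame-averaged input function).
BLOOD_POOL = "blood"

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid; center and semi-axes in mm (grid-center origin)."""

    center_mm: Tuple[float, float, float]
    radii_mm: Tuple[float, float, float]

    def contains(self, xyz_mm: np.ndarray) -> np.ndarray:
        d = (xyz_mm - np.asarray(self.center_mm)) / np.asarray(self.radii_mm)
        return np.sum(d * d, axis=-1) <= 1.0


@dataclass(frozen=True)
class Box:
    center_mm: Tuple[float, float, float]
    half_sizes_mm: Tuple[float, float, float]

    def contains(self, xyz_mm: np.ndarray) -> np.ndarray:
        d = np.abs(xyz_mm - np.asarray(self.center_mm))
        return np.all(d <= np.asarray(self.half_sizes_mm), axis=-1)


@dataclass(frozen=True)
class Tube:
    """Cylinder along z; circular cross-section of given radius in the x-y plane."""

    center_xy_mm: Tuple[float, float]
    radius_mm: float
    z_range_mm: Optional[Tuple[float, float]] = None  # None -> full grid

    def contains(self, xyz_mm: np.ndarray) -> np.ndarray:
        d = xyz_mm[..., :2] - np.asarray(self.center_xy_mm)
        inside = np.sum(d * d, axis=-1) <= self.radius_mm**2
        if self.z_range_mm is not None:
            z = xyz_mm[..., 2]
            inside &= (z >= self.z_range_mm[0]) & (z <= self.z_range_mm[1])
        return inside


@dataclass(frozen=True)
class Shell:
    """Spherical shell (rim) between inner and outer radius, in mm."""

    center_mm: Tuple[float, float, float]
    outer_radius_mm: float
    inner_radius_mm: float

    def __post_init__(self) -> None:
        if not 0 <= self.inner_radius_mm < self.outer_radius_mm:
            raise ValueError("need 0 <= inner radius < outer radius")

    def contains(self, xyz_mm: np.ndarray) -> np.ndarray:
        d = xyz_mm - np.asarray(self.center_mm)
        r2 = np.sum(d * d, axis=-1)
        return (r2 <= self.outer_radius_mm**2) & (r2 > self.inner_radius_mm**2)


Geometry = Union[Ellipsoid, Box, Tube, Shell]

#: Default reconstruction voxel size in mm.
DEFAULT_VOXEL_MM = (1.082, 1.082, 2.025)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of the synthetic brain.

    ``regions`` is an ordered list of (label, geometry); later entries
    overwrite earlier ones where they overlap. Every label must have an
    entry in ``kinetics`` (a :class:`TissueKineticParams`, or the
    :data:`BLOOD_POOL` sentinel for vascular labels). The implicit
    ``background`` label (0) is everything no geometry claims.
    """

    shape: Tuple[int, int, int]
    voxel_size_mm: Tuple[float, float, float]
    regions: Tuple[Tuple[str, Geometry], ...]
    kinetics: Dict[str, Union[TissueKineticParams, str]]
    input_function: InputFunction
    schedule: FrameSchedule
    psf_fwhm_mm: Tuple[float, float, float] = (6.0, 6.0, 6.0)
    noise_scale: float = 0.9
    injected_dose_MBq: float = 400.0
    body_weight_kg: float = 75.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if any(f < 0 for f in self.psf_fwhm_mm):
            raise ValueError("psf_fwhm_mm must be >= 0")
        labels = {name for name, _ in self.regions}
        missing = labels - set(self.kinetics) - {"background"}
        if missing:
            raise ValueError(f"regions without kinetics: {sorted(missing)}")
        if "background" not in self.kinetics:
            raise ValueError("kinetics must define the background label")

    @property
    def label_names(self) -> List[str]:
        names = ["background"]
        for name, _ in self.regions:
            if name not in names:
                names.append(name)
        return names


@dataclass(frozen=True)
class LabelMap:
    """Integer label image plus the label-id table."""

    data: np.ndarray  # int16, 3D
    voxel_size_mm: Tuple[float, float, float]
    ids: Dict[str, int]  # name -> integer label (background = 0)

    def mask(self, name: str) -> np.ndarray:
        return self.data == self.ids[name]


@dataclass(frozen=True)
class DynamicImage:
    """4D (x, y, z, frame) activity image in kBq/mL."""

    data: np.ndarray
    voxel_size_mm: Tuple[float, float, float]
    schedule: FrameSchedule
    unit: str = "kBq/mL"

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("DynamicImage data must be 4-D (x, y, z, frame)")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError("frame count must match the schedule")

    def scaled(self, factor: float) -> "DynamicImage":
        return replace(self, data=self.data * factor)


def _voxel_centers_mm(shape, voxel_size_mm) -> np.ndarray:
    """(nx, ny, nz, 3) voxel-center coordinates, origin at the grid center."""
    axes = [
        (np.arange(n) + 0.5 - n / 2.0) * v for n, v in zip(shape, voxel_size_mm)
    ]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack(g, axis=-1)


def build_label_map(spec: PhantomSpec) -> LabelMap:
    """Rasterize the region list into an integer label image.

    A voxel belongs to the last-listed geometry containing its center;
    unclaimed voxels are background (label 0). An empty region raises a
    warning, not an error.
    """
    xyz = _voxel_centers_mm(spec.shape, spec.voxel_size_mm)
    data = np.zeros(spec.shape, dtype=np.int16)
    ids = {"background": 0}
    next_id = 1
    for name, geom in spec.regions:
        if name not in ids:
            ids[name] = next_id
            next_id += 1
        inside = geom.contains(xyz)
        if not inside.any():
            warnings.warn(f"region '{name}' contains no voxel centers", stacklevel=2)
        data[inside] = ids[name]
    return LabelMap(data, spec.voxel_size_mm, ids)


def region_tacs(spec: PhantomSpec) -> Dict[str, TimeActivityCurve]:
    """Ground-truth frame-averaged TAC of every label (pre-blur, pre-noise)."""
    out: Dict[str, TimeActivityCurve] = {}
    mids = spec.schedule.mid_times_min
    for name in spec.label_names:
        kin = spec.kinetics[name]
        if kin == BLOOD_POOL:
            vals = frame_average(
                spec.input_function, spec.schedule, spec.input_function.node_times()
            )
            out[name] = TimeActivityCurve(mids, vals, unit="kBq/mL")
        else:
            out[name] = simulate_2tcm(kin, spec.input_function, spec.schedule)
    return out


def render_noiseless(spec: PhantomSpec) -> DynamicImage:
    """Render the noiseless dynamic image.

    Every voxel takes its label's frame-averaged TAC, then each frame is
    blurred with the stationary Gaussian PSF (partial-volume model).
    """
    labels = build_label_map(spec)
    tacs = region_tacs(spec)
    n_frames = spec.schedule.n_frames
    lut = np.zeros((max(labels.ids.values()) + 1, n_frames))
    for name, lid in labels.ids.items():
        lut[lid] = tacs[name].values
    img = lut[labels.data]  # (x, y, z, frame)
    sigma_vox = [
        f * FWHM_TO_SIGMA / v for f, v in zip(spec.psf_fwhm_mm, spec.voxel_size_mm)
    ]
    if any(s > 0 for s in sigma_vox):
        img = np.ascontiguousarray(img)
        for k in range(n_frames):
            img[..., k] = gaussian_filter(img[..., k], sigma=sigma_vox, mode="constant")
    return DynamicImage(img, spec.voxel_size_mm, spec.schedule)


def add_noise(
    img: DynamicImage, noise_scale: float, seed: int, clip_negative: bool = False
) -> DynamicImage:
    """Add count-dependent Gaussian noise, bit-reproducible for a given seed.

    Per voxel-frame, SD = noise_scale * sqrt(max(value, eps) / frame
    duration in minutes): variance proportional to activity and inversely
    proportional to frame duration, the standard post-reconstruction
    approximation. Negative values are kept by default (clipping would bias
    region means).
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    if noise_scale == 0:
        return img
    eps = 1e-6
    dur = img.schedule.durations_min
    sd = noise_scale * np.sqrt(np.maximum(img.data, eps) / dur)
    rng = np.random.default_rng(seed)
    data = img.data + rng.standard_normal(img.data.shape) * sd
    if clip_negative:
        data = np.maximum(data, 0.0)
    return replace(img, data=data)


def make_test_retest_pair(
    spec: PhantomSpec,
    seed_test: int,
    seed_retest: int,
    dose_jitter_fraction: float = 0.15,
    noiseless: Optional[DynamicImage] = None,
) -> Tuple[DynamicImage, DynamicImage, float]:
    """Simulate paired test-retest scans of one subject.

    Geometry and kinetics are shared; the retest injected activity is
    scaled by (1 + u), u ~ Uniform(-dose_jitter_fraction,
    +dose_jitter_fraction) (drawn from the pair's seeds), and the two
    scans get independent noise. Because all kinetics are linear in the
    input function, the retest noiseless image is an exact scalar multiple
    of the test one.

    Returns (test, retest, 1 + u). A precomputed ``noiseless`` render may
    be supplied to avoid re-rendering.
    """
    if seed_test == seed_retest:
        raise ValueError("test and retest seeds must differ")
    if noiseless is None:
        noiseless = render_noiseless(spec)
    u_rng = np.random.default_rng([seed_test, seed_retest])
    u = float(u_rng.uniform(-dose_jitter_fraction, dose_jitter_fraction))
    factor = 1.0 + u
    test = add_noise(noiseless, spec.noise_scale, seed_test)
    retest = add_noise(noiseless.scaled(factor), spec.noise_scale, seed_retest)
    return test, retest, factor


# ---------------------------------------------------------------------------
# default phantom


def default_input_function() -> InputFunction:
    """Slow-bolus whole-blood curve: linear rise to 40 kBq/mL at 1.5 min,
    then tri-exponential decay (fast redistribution, renal/hepatic
    clearance, slow terminal washout)."""
    return InputFunction(
        prepeak_times=[0.0, 1.5],
        prepeak_values=[0.0, 40.0],
        amplitudes=[24.0, 12.0, 4.0],
        rates=[3.0, 0.4, 0.012],
    )


def default_kinetics() -> Dict[str, Union[TissueKineticParams, str]]:
    """Region kinetics with V_T ordering TH > lesion rim > CGM > WM > core."""
    return {
        "background": TissueKineticParams(K1=0.0, k2=1.0, vB=0.0),
        # white matter: low delivery, slow clearance, little specific
        # binding; its V_T sits just below the reference gray's, so its
        # BP_ND is near zero (uptake contrast is delivery-limited)
        "wm": TissueKineticParams(K1=0.03, k2=0.05, k3=0.02, k4=0.04, vB=0.05),  # V_T 0.90
        # cortical gray: brisk delivery/clearance, minimal specific
        # binding — the normal-gray reference class
        "cgm": TissueKineticParams(K1=0.096, k2=0.12, k3=0.008, k4=0.04, vB=0.05),  # V_T 0.96
        # thalamus: gray-matter delivery with strong specific binding
        "th": TissueKineticParams(K1=0.12, k2=0.12, k3=0.084, k4=0.04, vB=0.05),  # V_T 3.10
        # chronic lesion: hypocellular core, modestly activated rim
        "lesion_core": TissueKineticParams(K1=0.02, k2=0.05, k3=0.01, k4=0.04, vB=0.05),  # 0.50
        "lesion_rim": TissueKineticParams(K1=0.05, k2=0.08, k3=0.025, k4=0.04, vB=0.05),  # 1.02
        "carotid": BLOOD_POOL,
    }


#: The lesion-volume range (cm^3) sampled by the default phantom.
LESION_VOLUME_RANGE_CM3 = (0.08, 1.691)

#: Fixed lesion centers (mm) in the white matter, away from the thalamus.
_LESION_CENTERS_MM = ((22.0, 11.0, 0.0), (-22.0, 11.0, 0.0), (22.0, -11.0, 0.0), (-22.0, -11.0, 0.0))


def default_phantom(
    shape: Tuple[int, int, int] = (96, 96, 48),
    scale: float = 1.0,
    seed: int = 20180809,
    n_lesions: int = 4,
    psf_fwhm_mm: float = 6.0,
    noise_scale: float = 0.9,
) -> PhantomSpec:
    """The standard test phantom.

    One brain-sized ellipsoid of cortical gray matter enclosing a
    white-matter ellipsoid that contains a high-binding thalamus and
    ``n_lesions`` rim/core lesion shells; two 4-mm-diameter carotid tubes
    run along z outside the brain. Lesion volumes are sampled log-uniformly
    over 0.08-1.691 cm^3 with the spec seed. ``scale`` shrinks all
    non-lesion geometry (for quick small-grid runs).

    The V_T ordering is TH > CGM > WM with the lesion rim above WM, so the
    thalamic VOI suffers spill-out (its mean rises under erosion) while the
    WM VOI, bordered by hotter CGM and TH, suffers spill-in (its mean falls
    under erosion).
    """
    s = scale
    regions: List[Tuple[str, Geometry]] = [
        ("cgm", Ellipsoid((0, 0, 0), (45 * s, 41 * s, 37 * s))),
        ("wm", Ellipsoid((0, 0, 0), (33 * s, 29 * s, 25 * s))),
        ("th", Ellipsoid((0, 0, 0), (14 * s, 16 * s, 12 * s))),
    ]
    rng = np.random.default_rng(seed)
    lo, hi = LESION_VOLUME_RANGE_CM3
    vols = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_lesions))  # cm^3
    for j in range(n_lesions):
        r_out = (3.0 * vols[j] * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
        center = tuple(c * s for c in _LESION_CENTERS_MM[j % len(_LESION_CENTERS_MM)])
        regions.append((f"lesion_core_{j}", Ellipsoid(center, (0.6 * r_out,) * 3)))
        regions.append((f"lesion_rim_{j}", Shell(center, r_out, 0.6 * r_out)))
    # two carotid tubes, 4 mm diameter, anterior to the brain
    for x in (-10.0, 10.0):
        regions.append(("carotid", Tube((x * s, -47.0 * s), 2.0)))

    kin = default_kinetics()
    kinetics: Dict[str, Union[TissueKineticParams, str]] = {
        k: v for k, v in kin.items() if k not in ("lesion_core", "lesion_rim")
    }
    for j in range(n_lesions):
        kinetics[f"lesion_core_{j}"] = kin["lesion_core"]
        kinetics[f"lesion_rim_{j}"] = kin["lesion_rim"]

    return PhantomSpec(
        shape=shape,
        voxel_size_mm=DEFAULT_VOXEL_MM,
        regions=tuple(regions),
        kinetics=kinetics,
        input_function=default_input_function(),
        schedule=FrameSchedule.brain_60min(),
        psf_fwhm_mm=(psf_fwhm_mm,) * 3,
        noise_scale=noise_scale,
        seed=seed,
    )


def widespread_activation_phantom(**kwargs) -> PhantomSpec:
    """Default phantom with uniformly elevated binding everywhere.

    All brain tissue takes the high-binding (thalamus-like) kinetics,
    emulating widespread microglial activation; supervised-cluster
    reference extraction is expected to fail on this phantom because no
    voxel resembles the normal-gray class.
    """
    spec = default_phantom(**kwargs)
    hot = spec.kinetics["th"]
    kinetics = {
        name: (hot if isinstance(k, TissueKineticParams) and name != "background" else k)
        for name, k in spec.kinetics.items()
    }
    return replace(spec, kinetics=kinetics)
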