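import numpy as np
import pytest

from pkpet.kinetics import analytic_vt
from pkpet.phantom import (
    BLOOD_POOL,
    Box,
    Ellipsoid,
    PhantomSpec,
    Shell,
    add_noise,
    build_label_map,
    default_input_function,
    default_kinetics,
    default_phantom,
    make_test_retest_pair,
    region_tacs,
    render_noiseless,
    widespread_activation_phantom,
)
from pkpet.frames import FrameSchedule
from pkpet.kinetics import TissueKineticParams


def minimal_spec(**overrides):
    base = dict(
        shape=(40, 40, 20),
        voxel_size_mm=(1.0, 1.0, 1.0),
        regions=(("blob", Ellipsoid((0, 0, 0), (8.0, 8.0, 6.0))),),
        kinetics={
            "background": TissueKineticParams(K1=0.0, k2=1.0, vB=0.0),
            "blob": TissueKineticParams(K1=0.1, k2=0.1, k3=0.05, k4=0.05, vB=0.05),
        },
        input_function=default_input_function(),
        schedule=FrameSchedule.brain_60min(),
        psf_fwhm_mm=(0.0, 0.0, 0.0),
        noise_scale=0.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def test_sphere_volume_within_2pct():
    spec = minimal_spec(
        shape=(80, 80, 40),
        regions=(("ball", Ellipsoid((0, 0, 0), (12.0, 12.0, 12.0))),),
        kinetics={
            "background": TissueKineticParams(K1=0.0, k2=1.0, vB=0.0),
            "ball": TissueKineticParams(K1=0.1, k2=0.1),
        },
    )
    lm = build_label_map(spec)
    vol = lm.mask("ball").sum()  # 1 mm^3 voxels
    assert vol == pytest.approx(4.0 / 3.0 * np.pi * 12.0**3, rel=0.02)


def test_box_volume_exact():
    spec = minimal_spec(
        regions=(("box", Box((0, 0, 0), (5.0, 4.0, 3.0))),),
        kinetics={
            "background": TissueKineticParams(K1=0.0, k2=1.0, vB=0.0),
            "box": TissueKineticParams(K1=0.1, k2=0.1),
        },
    )
    lm = build_label_map(spec)
    # voxel centers at half-integers; a 10x8x6 mm box covers 10*8*6 centers
    assert lm.mask("box").sum() == 10 * 8 * 6


def test_shell_is_sphere_difference():
    common = dict(center_mm=(0, 0, 0))
    shell = Shell(outer_radius_mm=7.0, inner_radius_mm=4.0, **common)
    outer = Ellipsoid((0, 0, 0), (7.0, 7.0, 7.0))
    inner = Ellipsoid((0, 0, 0), (4.0, 4.0, 4.0))
    kin = {
        "background": TissueKineticParams(K1=0.0, k2=1.0, vB=0.0),
        "a": TissueKineticParams(K1=0.1, k2=0.1),
        "b": TissueKineticParams(K1=0.1, k2=0.1),
    }
    lm_shell = build_label_map(minimal_spec(regions=(("a", shell),), kinetics=kin))
    lm_diff = build_label_map(
        minimal_spec(regions=(("a", outer), ("b", inner)), kinetics=kin)
    )
    assert np.array_equal(lm_shell.mask("a"), lm_diff.mask("a"))


def test_later_regions_overwrite():
    kin = {
        "background": TissueKineticParams(K1=0.0, k2=1.0, vB=0.0),
        "big": TissueKineticParams(K1=0.1, k2=0.1),
        "small": TissueKineticParams(K1=0.2, k2=0.1),
    }
    spec = minimal_spec(
        regions=(
            ("big", Ellipsoid((0, 0, 0), (8.0, 8.0, 6.0))),
            ("small", Ellipsoid((0, 0, 0), (3.0, 3.0, 3.0))),
        ),
        kinetics=kin,
    )
    lm = build_label_map(spec)
    assert not np.any(lm.mask("big") & lm.mask("small"))
    assert lm.mask("small").sum() > 0


def test_missing_kinetics_rejected():
    with pytest.raises(ValueError):
        minimal_spec(kinetics={"background": TissueKineticParams(K1=0.0, k2=1.0, vB=0.0)})


def test_render_without_psf_is_exact_lut():
    spec = minimal_spec()
    img = render_noiseless(spec)
    lm = build_label_map(spec)
    tacs = region_tacs(spec)
    inside = img.data[lm.mask("blob")]
    assert np.allclose(inside, tacs["blob"].values, rtol=1e-12)
    assert np.all(img.data[lm.mask("background")] == 0.0)


def test_psf_conserves_mass():
    spec = minimal_spec(psf_fwhm_mm=(4.0, 4.0, 4.0))
    sharp = render_noiseless(minimal_spec())
    blurred = render_noiseless(spec)
    # object is far from the grid edge, so constant-mode truncation loss
    # stays small; Gaussian smoothing preserves the integral
    f = -1
    assert blurred.data[..., f].sum() == pytest.approx(
        sharp.data[..., f].sum(), rel=0.005
    )


def test_psf_spill_directions():
    spec = minimal_spec(psf_fwhm_mm=(4.0, 4.0, 4.0))
    sharp = render_noiseless(minimal_spec())
    blurred = render_noiseless(spec)
    lm = build_label_map(spec)
    f = -1
    # hot object loses to the cold surround
    assert blurred.data[..., f][lm.mask("blob")].mean() < sharp.data[..., f][
        lm.mask("blob")
    ].mean()
    assert blurred.data[..., f][lm.mask("background")].mean() > 0.0


def test_noise_sd_law():
    spec = minimal_spec(shape=(60, 60, 40))
    img = render_noiseless(spec)
    noisy = add_noise(img, noise_scale=0.7, seed=123)
    lm = build_label_map(spec)
    bg = lm.mask("background")
    for f in (0, 10, 21):
        resid = (noisy.data[..., f] - img.data[..., f])[bg]
        dur = img.schedule.durations_min[f]
        expected_sd = 0.7 * np.sqrt(1e-6 / dur)  # background value is 0 -> eps
        assert resid.std() == pytest.approx(expected_sd, rel=0.03)
        assert abs(resid.mean()) < 5 * expected_sd / np.sqrt(bg.sum())
    # activity-dependent part, inside the object
    blob = lm.mask("blob")
    f = 21
    resid = (noisy.data[..., f] - img.data[..., f])[blob]
    v = img.data[..., f][blob]
    z = resid / (0.7 * np.sqrt(np.maximum(v, 1e-6) / img.schedule.durations_min[f]))
    assert z.std() == pytest.approx(1.0, rel=0.05)


def test_noise_deterministic_per_seed():
    spec = minimal_spec()
    img = render_noiseless(spec)
    a = add_noise(img, 0.5, seed=9)
    b = add_noise(img, 0.5, seed=9)
    c = add_noise(img, 0.5, seed=10)
    assert np.array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)


def test_retest_pair_scale_propagation():
    spec = minimal_spec(noise_scale=0.0)
    noiseless = render_noiseless(spec)
    test, retest, factor = make_test_retest_pair(
        spec, 11, 12, dose_jitter_fraction=0.1, noiseless=noiseless
    )
    assert np.allclose(retest.data, factor * test.data, rtol=1e-12)
    assert abs(factor - 1.0) <= 0.1


def test_retest_pair_seed_validation():
    spec = minimal_spec()
    with pytest.raises(ValueError):
        make_test_retest_pair(spec, 5, 5)


def test_default_phantom_vt_ordering():
    kin = default_kinetics()
    vts = {k: analytic_vt(p) for k, p in kin.items()
           if p != BLOOD_POOL and p.K1 > 0}
    assert vts["th"] > vts["lesion_rim"] > vts["cgm"] > vts["wm"] > vts["lesion_core"]


def test_default_phantom_structure(default_spec):
    lm = build_label_map(default_spec)
    names = default_spec.label_names
    assert {"cgm", "wm", "th", "carotid"}.issubset(names)
    assert sum(1 for n in names if n.startswith("lesion_rim")) == 4
    # carotid tube diameter ~4 mm: cross-section area per slice ~ pi*2^2
    car = lm.mask("carotid")
    per_slice = car.sum() / car.shape[2] / 2  # two tubes, full z extent
    vx_area = default_spec.voxel_size_mm[0] * default_spec.voxel_size_mm[1]
    assert per_slice * vx_area == pytest.approx(np.pi * 4.0, rel=0.15)


def test_region_tacs_blood_pool(default_spec):
    tacs = region_tacs(default_spec)
    from pkpet.kinetics import frame_average

    blood = frame_average(
        default_spec.input_function,
        default_spec.schedule,
        nodes_min=default_spec.input_function.node_times(),
    )
    assert np.allclose(tacs["carotid"].values, blood, rtol=1e-12)


def test_widespread_phantom_uniform_kinetics():
    spec = widespread_activation_phantom(shape=(48, 48, 24), scale=0.5, n_lesions=2)
    hot = spec.kinetics["th"]
    for name, p in spec.kinetics.items():
        if name in ("background", "carotid"):
            continue
        assert p == hot
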