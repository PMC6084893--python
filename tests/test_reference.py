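import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from pkpet.phantom import add_noise, render_noiseless, widespread_activation_phantom
from pkpet.reference import (
    KineticClassLibrary,
    decompose_curves,
    decompose_voxel,
    extract_reference_curve,
    library_from_phantom,
    nnls_fixed_design,
    normalize_curve,
)
from pkpet.reliability import phantom_masks
from pkpet.tac import TimeActivityCurve, auc
from pkpet.voi import EmptyMaskError, RegionMask


def test_normalize_curve_unit_area():
    t = np.linspace(1.0, 60.0, 22)
    tac = TimeActivityCurve(t, np.exp(-0.05 * t) * 7.0)
    n = normalize_curve(tac)
    assert np.trapezoid(n.values, t) == pytest.approx(1.0, rel=1e-12)


def test_normalize_rejects_negative_or_zero():
    t = np.array([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        normalize_curve(TimeActivityCurve(t, np.array([1.0, -0.5, 1.0])))
    with pytest.raises(ValueError):
        normalize_curve(TimeActivityCurve(t, np.zeros(3)))


def toy_library():
    t = np.linspace(1.0, 60.0, 22)
    raw = np.stack(
        [
            np.exp(-0.02 * t),
            np.exp(-0.005 * t),
            t / (5.0 + t),
            np.exp(-0.3 * t) + 0.01,
        ]
    )
    w = np.zeros_like(t)
    dt = np.diff(t)
    w[:-1] += dt / 2
    w[1:] += dt / 2
    curves = raw / (raw @ w)[:, None]
    return KineticClassLibrary(t, curves)


def test_library_validation():
    lib = toy_library()
    with pytest.raises(ValueError):  # non-unit area
        KineticClassLibrary(lib.times, lib.curves * 2.0)
    with pytest.raises(ValueError):  # identical classes
        KineticClassLibrary(lib.times, np.stack([lib.curves[0]] * 4))
    with pytest.raises(ValueError):  # unknown reference class
        KineticClassLibrary(lib.times, lib.curves, reference_class="nope")


def test_nnls_matches_scipy():
    rng = np.random.default_rng(5)
    A = np.abs(rng.normal(size=(22, 4)))
    Y = np.abs(rng.normal(size=(300, 22)))
    ours = nnls_fixed_design(A, Y)
    for i in range(0, 300, 7):
        ref, _ = scipy_nnls(A, Y[i])
        fit_ours = A @ ours[i] - Y[i]
        fit_ref = A @ ref - Y[i]
        assert fit_ours @ fit_ours == pytest.approx(fit_ref @ fit_ref, abs=1e-9)


def test_decompose_pure_class_voxel():
    lib = toy_library()
    for k in range(4):
        tac = TimeActivityCurve(lib.times, 5.0 * lib.curves[k])
        coefs = decompose_voxel(tac, lib)
        assert coefs[k] == pytest.approx(1.0, abs=1e-8)
        assert coefs.sum() == pytest.approx(1.0)


def test_decompose_known_mixture():
    lib = toy_library()
    mix = 0.7 * lib.curves[0] + 0.3 * lib.curves[1]
    coefs = decompose_voxel(TimeActivityCurve(lib.times, mix), lib)
    assert coefs[0] == pytest.approx(0.7, abs=1e-6)
    assert coefs[1] == pytest.approx(0.3, abs=1e-6)


def test_decompose_zero_voxel_gives_zeros():
    lib = toy_library()
    coefs = decompose_curves(np.zeros((3, lib.times.size)), lib)
    assert np.all(coefs == 0.0)


def test_extraction_recovers_reference_noiseless(default_spec, noiseless_default,
                                                 default_masks, default_library):
    from pkpet.phantom import region_tacs

    res = extract_reference_curve(
        noiseless_default, default_masks["brain"], default_library
    )
    assert res.status == "ok"
    truth = region_tacs(default_spec)["cgm"]
    ratio = auc(res.tac, 1.0, 60.0) / auc(truth, 1.0, 60.0)
    assert ratio == pytest.approx(1.0, abs=0.05)


def test_extraction_noisy_within_5pct(default_spec, noiseless_default,
                                      default_masks, default_library):
    from pkpet.phantom import region_tacs

    truth = region_tacs(default_spec)["cgm"]
    noisy = add_noise(noiseless_default, default_spec.noise_scale, seed=31)
    res = extract_reference_curve(noisy, default_masks["brain"], default_library)
    assert res.status == "ok"
    ratio = auc(res.tac, 1.0, 60.0) / auc(truth, 1.0, 60.0)
    assert ratio == pytest.approx(1.0, abs=0.05)
    assert 0 < res.selected_fraction <= 1.0
    assert res.weight_mass > 0


def test_extraction_fails_on_widespread_activation(default_library):
    spec = widespread_activation_phantom()
    img = add_noise(render_noiseless(spec), spec.noise_scale, seed=17)
    masks = phantom_masks(spec)
    res = extract_reference_curve(img, masks["brain"], default_library)
    assert res.status == "failed"
    assert res.tac is None
    assert res.selected_fraction < 0.01


def test_extraction_threshold_monotonicity(noiseless_default, default_masks,
                                           default_library):
    counts = []
    for thr in (0.5, 0.7, 0.9):
        res = extract_reference_curve(
            noiseless_default, default_masks["brain"], default_library,
            coef_threshold=thr,
        )
        counts.append(res.selected_voxel_count)
    assert counts[0] >= counts[1] >= counts[2]


def test_extraction_empty_mask(noiseless_default, default_library):
    empty = RegionMask(
        np.zeros(noiseless_default.data.shape[:3], dtype=bool),
        noiseless_default.voxel_size_mm,
        "empty",
    )
    with pytest.raises(EmptyMaskError):
        extract_reference_curve(noiseless_default, empty, default_library)


def test_library_from_phantom_classes(default_spec, default_library):
    assert default_library.class_names == (
        "reference_gray", "white", "high_binding", "blood",
    )
    assert default_library.reference_index == 0
    w = np.zeros_like(default_library.times)
    dt = np.diff(default_library.times)
    w[:-1] += dt / 2
    w[1:] += dt / 2
    assert np.allclose(default_library.curves @ w, 1.0)
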