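"""Imaging infrastructure: smoothing, sphere extraction, first-level GLM."""

import numpy as np
import pytest

from compmap import (
    TaskDesign,
    VolumetricImage,
    build_design_matrix,
    default_affine,
    double_gamma_hrf,
    extract_sphere_timeseries,
    first_level_glm,
    smooth,
)
from compmap.errors import (
    CollinearityError,
    CoordinateError,
    DesignError,
    EmptyRegionError,
    UnsupportedGeometryError,
)
from compmap.images import FWHM_TO_SIGMA


def _img(shape=(12, 10, 8), voxel=3.0, data=None, rng=None):
    if data is None:
        data = (rng or np.random.default_rng(0)).standard_normal(shape)
    return VolumetricImage(data, default_affine(data.shape[:3], voxel))


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def test_smooth_zero_fwhm_is_identity(rng):
    img = _img(rng=rng)
    out = smooth(img, 0.0)
    np.testing.assert_array_equal(out.data, img.data)


def test_smooth_constant_image_unchanged():
    img = _img(data=np.full((9, 9, 9), 3.7))
    out = smooth(img, 6.0)
    np.testing.assert_allclose(out.data, 3.7, atol=1e-12)


def test_smooth_impulse_matches_analytic_gaussian():
    """Impulse response equals the separable normalized sampled Gaussian."""
    shape, voxel, fwhm = (15, 15, 15), 3.0, 6.0
    data = np.zeros(shape)
    data[7, 7, 7] = 1.0
    out = smooth(_img(shape=shape, voxel=voxel, data=data), fwhm)

    sigma = fwhm * FWHM_TO_SIGMA / voxel  # in voxels
    radius = int(4.0 * sigma + 0.5)  # same truncation as the implementation
    x = np.arange(-radius, radius + 1)
    w = np.exp(-(x**2) / (2 * sigma**2))
    w /= w.sum()
    kernel3d = w[:, None, None] * w[None, :, None] * w[None, None, :]
    expected = np.zeros(shape)
    sl = slice(7 - radius, 7 + radius + 1)
    expected[sl, sl, sl] = kernel3d
    np.testing.assert_allclose(out.data, expected, atol=1e-6)


def test_smooth_conserves_total_intensity_interior():
    """Total intensity of a nonnegative interior source is conserved to 0.1%."""
    shape = (24, 24, 24)
    data = np.zeros(shape)
    data[10:14, 10:14, 10:14] = 2.0
    out = smooth(_img(shape=shape, voxel=3.0, data=data), 6.0)
    assert out.data.sum() == pytest.approx(data.sum(), rel=1e-3)


def test_smooth_linear_and_shift_equivariant(rng):
    a = rng.standard_normal((10, 10, 10))
    b = rng.standard_normal((10, 10, 10))
    aff = default_affine((10, 10, 10), 3.0)
    s = lambda d: smooth(VolumetricImage(d, aff), 5.0).data
    np.testing.assert_allclose(s(2.0 * a - 3.0 * b), 2.0 * s(a) - 3.0 * s(b), atol=1e-10)
    # shifting an interior impulse shifts the response
    d1 = np.zeros((16, 16, 16))
    d2 = np.zeros((16, 16, 16))
    d1[8, 8, 8] = 1.0
    d2[9, 8, 8] = 1.0
    aff2 = default_affine((16, 16, 16), 3.0)
    r1 = smooth(VolumetricImage(d1, aff2), 6.0).data
    r2 = smooth(VolumetricImage(d2, aff2), 6.0).data
    np.testing.assert_allclose(np.roll(r1, 1, axis=0), r2, atol=1e-12)


def test_smooth_4d_framewise(rng):
    data = rng.standard_normal((8, 8, 8, 5))
    img = VolumetricImage(data, default_affine((8, 8, 8), 3.0))
    out = smooth(img, 6.0)
    for t in range(5):
        frame = smooth(VolumetricImage(data[..., t], img.affine), 6.0)
        np.testing.assert_allclose(out.data[..., t], frame.data, atol=1e-12)


def test_smooth_rejects_sheared_affine(rng):
    aff = default_affine((8, 8, 8), 3.0)
    aff[0, 1] = 1.0  # shear
    img = VolumetricImage(rng.standard_normal((8, 8, 8)), aff)
    with pytest.raises(UnsupportedGeometryError):
        smooth(img, 6.0)


# ---------------------------------------------------------------------------
# sphere extraction
# ---------------------------------------------------------------------------


def test_sphere_single_voxel(rng):
    img = VolumetricImage(rng.standard_normal((6, 6, 6, 11)), default_affine((6, 6, 6), 4.0))
    center = img.voxel_to_mm([2, 3, 1])[0]
    series, n = extract_sphere_timeseries(img, center, radius_mm=1.5)
    assert n == 1
    np.testing.assert_array_equal(series, img.data[2, 3, 1, :])


def test_sphere_matches_brute_force_scan(rng):
    """Sphere membership equals an exhaustive voxel-centre distance scan."""
    shape = (10, 9, 8)
    aff = np.diag([3.0, 3.3, 4.0, 1.0])
    aff[:3, 3] = (-12.0, -10.0, -14.0)
    img = VolumetricImage(rng.standard_normal(shape + (7,)), aff)
    center, radius = np.array([1.0, -2.0, 3.0]), 6.0
    series, n = extract_sphere_timeseries(img, center, radius)

    picked = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                mm = aff[:3, :3] @ [i, j, k] + aff[:3, 3]
                if np.linalg.norm(mm - center) <= radius:
                    picked.append(img.data[i, j, k, :])
    assert n == len(picked) > 1
    np.testing.assert_allclose(series, np.mean(picked, axis=0), atol=1e-12)


def test_sphere_face_neighbors_at_matching_radius(rng):
    """A 4 mm sphere on a 4 mm grid picks the 7-voxel face-neighbour cross."""
    img = VolumetricImage(rng.standard_normal((9, 9, 9, 4)), default_affine((9, 9, 9), 4.0))
    center = img.voxel_to_mm([4, 4, 4])[0]
    _, n = extract_sphere_timeseries(img, center, radius_mm=4.0)
    assert n == 7


def test_sphere_constant_image(rng):
    data = np.broadcast_to(rng.standard_normal(6), (5, 5, 5, 6)).copy()
    img = VolumetricImage(data, default_affine((5, 5, 5), 4.0))
    series, _ = extract_sphere_timeseries(img, [0, 0, 0], radius_mm=5.0)
    np.testing.assert_allclose(series, data[0, 0, 0, :], atol=1e-12)


def test_sphere_errors(rng):
    img = VolumetricImage(rng.standard_normal((5, 5, 5, 4)), default_affine((5, 5, 5), 4.0))
    with pytest.raises(CoordinateError):
        extract_sphere_timeseries(img, [500, 0, 0], radius_mm=4.0)
    off_center = img.voxel_to_mm([2, 2, 2])[0] + 2.0  # between voxel centres
    with pytest.raises(EmptyRegionError):
        extract_sphere_timeseries(img, off_center, radius_mm=0.5)


# ---------------------------------------------------------------------------
# HRF and first-level GLM
# ---------------------------------------------------------------------------


def test_hrf_shape_and_nilearn_crosscheck():
    """Double-gamma peaks near 6 s, undershoots, matches nilearn's SPM HRF."""
    t = np.arange(0, 32, 0.1)
    h = double_gamma_hrf(t)
    assert t[np.argmax(h)] == pytest.approx(5.0, abs=1.5)
    assert h.min() < 0  # undershoot
    assert h.max() == pytest.approx(1.0)

    nilearn = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
    ref = nilearn.spm_hrf(0.1, oversampling=1, time_length=32)
    m = min(len(ref), len(h))
    corr = np.corrcoef(h[:m], ref[:m])[0, 1]
    assert corr > 0.99


def _design(n_volumes=60, tr=2.5, motion=None):
    return TaskDesign(
        onsets_s=[10, 60, 110], durations_s=[20, 20, 20],
        conditions=["2back", "1back", "2back"],
        tr_s=tr, n_volumes=n_volumes, motion=motion,
    )


def test_glm_noiseless_recovery(rng):
    """Exact contrast recovery when the data are a pure design response."""
    design = _design()
    X, names = build_design_matrix(design)
    shape = (6, 5, 4)
    B = rng.standard_normal((X.shape[1], np.prod(shape)))
    Y = X @ B  # retained frames
    full = np.concatenate([rng.standard_normal((4, Y.shape[1])), Y], axis=0)
    img = VolumetricImage(full.T.reshape(shape + (64,)), default_affine(shape, 4.0))
    cmap = first_level_glm(img, design, {"2back": 1.0, "1back": -1.0})
    w = np.array([{"2back": 1.0, "1back": -1.0}.get(nm, 0.0) for nm in names])
    np.testing.assert_allclose(cmap.data.ravel(), w @ B, atol=1e-8)


def test_glm_equals_pseudoinverse_oracle(rng):
    design = _design()
    shape = (5, 4, 3)
    data = rng.standard_normal(shape + (64,))
    img = VolumetricImage(data, default_affine(shape, 4.0))
    cmap = first_level_glm(img, design, {"2back": 1.0, "1back": -1.0})
    X, names = build_design_matrix(design)
    w = np.array([{"2back": 1.0, "1back": -1.0}.get(nm, 0.0) for nm in names])
    Y = data[..., 4:].reshape(-1, 60).T
    expected = w @ (np.linalg.pinv(X) @ Y)
    np.testing.assert_allclose(cmap.data.ravel(), expected, atol=1e-8)


def test_glm_motion_regression_removes_leakage(rng):
    """Motion signal scaled into the data leaves the task contrast unchanged."""
    motion = np.cumsum(rng.normal(0, 0.05, (60, 6)), axis=0)
    design = _design(motion=motion)
    shape = (4, 4, 3)
    clean = rng.standard_normal(shape + (64,))
    img_clean = VolumetricImage(clean, default_affine(shape, 4.0))
    dirty = clean.copy()
    dirty[..., 4:] += 3.0 * motion[:, 2]  # inject one motion trace everywhere
    img_dirty = VolumetricImage(dirty, default_affine(shape, 4.0))
    weights = {"2back": 1.0, "1back": -1.0}
    c1 = first_level_glm(img_clean, design, weights)
    c2 = first_level_glm(img_dirty, design, weights)
    np.testing.assert_allclose(c1.data, c2.data, atol=1e-8)


def test_glm_pure_noise_contrast_variance_matches_theory(rng):
    """OLS theory: var(w'beta_hat) = sigma^2 w'(X'X)^-1 w for unit noise."""
    design = _design(n_volumes=80)
    shape = (20, 20, 10)  # 4000 voxels
    data = rng.standard_normal(shape + (84,))
    img = VolumetricImage(data, default_affine(shape, 4.0))
    cmap = first_level_glm(img, design, {"2back": 1.0, "1back": -1.0})
    X, names = build_design_matrix(design)
    w = np.array([{"2back": 1.0, "1back": -1.0}.get(nm, 0.0) for nm in names])
    theory = w @ np.linalg.inv(X.T @ X) @ w
    empirical = cmap.data.var()
    assert abs(cmap.data.mean()) < 3 * np.sqrt(theory / cmap.data.size) * 2
    assert empirical == pytest.approx(theory, rel=0.10)


def test_glm_rank_deficient_design_names_columns(rng):
    design = _design()
    X, _ = build_design_matrix(design)
    # a nuisance regressor duplicating a condition column
    design.nuisance["dup"] = X[:, 0].copy()
    img = VolumetricImage(rng.standard_normal((3, 3, 3, 64)), default_affine((3, 3, 3), 4.0))
    with pytest.raises(CollinearityError):
        first_level_glm(img, design, {"2back": 1.0})


def test_glm_design_validation(rng):
    img = VolumetricImage(rng.standard_normal((3, 3, 3, 50)), default_affine((3, 3, 3), 4.0))
    with pytest.raises(DesignError):
        first_level_glm(img, _design(n_volumes=60), {"2back": 1.0})  # 46 != 60
    with pytest.raises(DesignError):
        TaskDesign(onsets_s=[100], durations_s=[100], conditions=["a"],
                   tr_s=2.5, n_volumes=60)  # runs past scan end
    with pytest.raises(DesignError):
        TaskDesign(onsets_s=[0], durations_s=[10], conditions=["a"],
                   tr_s=2.5, n_volumes=60, motion=np.zeros((60, 5)))
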