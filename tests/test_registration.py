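import numpy as np
import pytest

from roit.imagio import Image2D
from roit.registration import (
    LandmarkPair,
    LandmarkSet,
    TPSTransform,
    apply_transform,
    fit_tps,
    read_landmarks_csv,
    warp_image,
    write_landmarks_csv,
)


def random_landmarks(rng, k, scale=200.0):
    return LandmarkSet.from_arrays(rng.uniform(0, scale, (k, 2)),
                                   rng.uniform(0, scale, (k, 2)))


# ------------------------------------------------------------- fitting ---

def test_identity_pairs_give_identity_map(rng):
    pts = rng.uniform(0, 100, (8, 2))
    t = fit_tps(LandmarkSet.from_arrays(pts, pts))
    probe = rng.uniform(-50, 150, (40, 2))
    np.testing.assert_allclose(apply_transform(t, probe), probe, atol=1e-9)


def test_three_landmark_fit_is_pure_affine():
    t = fit_tps(LandmarkSet.from_arrays([[0, 0], [10, 0], [0, 10]],
                                        [[0, 0], [20, 0], [0, 20]]))
    assert np.abs(t.weights).max() < 1e-9
    np.testing.assert_allclose(t.affine, [[0, 2, 0], [0, 0, 2]], atol=1e-9)


def test_exact_interpolation_at_lambda_zero(rng):
    for k in (4, 10, 30):
        lm = random_landmarks(rng, k)
        t = fit_tps(lm, lambda_reg=0.0) if k <= 30 else None
        mov, fix = lm.arrays()
        np.testing.assert_allclose(apply_transform(t, mov), fix, atol=1e-6)


def test_tps_side_conditions(rng):
    lm = random_landmarks(rng, 12)
    t = fit_tps(lm)
    mov, _ = lm.arrays()
    assert np.abs(t.weights.sum(axis=0)).max() < 1e-8
    assert np.abs(t.weights.T @ mov).max() < 1e-8


def test_matches_independent_thin_plate_interpolator(rng):
    """Cross-check against scipy's RBF thin-plate interpolator (kernel
    r^2 log r, i.e. half of r^2 log r^2 — an equivalent spline family, so
    the interpolants coincide)."""
    from scipy.interpolate import RBFInterpolator

    lm = random_landmarks(rng, 15)
    mov, fix = lm.arrays()
    t = fit_tps(lm)
    ref = RBFInterpolator(mov, fix, kernel="thin_plate_spline", smoothing=0.0)
    probe = rng.uniform(-20, 220, (100, 2))
    np.testing.assert_allclose(apply_transform(t, probe), ref(probe),
                               atol=1e-6)


def test_regularization_residual_monotone(rng):
    lm = random_landmarks(rng, 15)
    mov, fix = lm.arrays()
    rms = []
    for lam in (0.0, 1.0, 10.0, 100.0, 1000.0):
        t = fit_tps(lm, lambda_reg=lam)
        res = apply_transform(t, mov) - fix
        rms.append(np.sqrt((res ** 2).sum(axis=1).mean()))
    assert all(a <= b + 1e-9 for a, b in zip(rms, rms[1:]))


def test_degenerate_landmark_sets_rejected():
    with pytest.raises(ValueError, match="at least 3"):
        fit_tps(LandmarkSet.from_arrays([[0, 0], [1, 1]], [[0, 0], [1, 1]]))
    with pytest.raises(ValueError, match="collinear"):
        fit_tps(LandmarkSet.from_arrays([[0, 0], [5, 5], [10, 10]],
                                        [[0, 0], [5, 5], [10, 10]]))
    with pytest.raises(ValueError, match="duplicate"):
        fit_tps(LandmarkSet.from_arrays([[0, 0], [0, 0], [10, 0], [0, 10]],
                                        [[0, 0], [1, 1], [10, 0], [0, 10]]))
    with pytest.raises(ValueError):
        fit_tps(LandmarkSet.from_arrays([[0, 0], [1, 0], [0, 1]],
                                        [[0, 0], [1, 0], [0, 1]]),
                lambda_reg=-1.0)


def test_inactive_pairs_excluded(rng):
    pts = rng.uniform(0, 100, (5, 2))
    pairs = [LandmarkPair(f"p{i}", i != 4, tuple(pts[i]), tuple(pts[i]))
             for i in range(4)]
    # active identity pairs + one inactive pair that would break identity
    pairs.append(LandmarkPair("bad", False, tuple(pts[4]),
                              (pts[4][0] + 50, pts[4][1])))
    t = fit_tps(LandmarkSet(tuple(pairs)))
    np.testing.assert_allclose(apply_transform(t, pts[:4]), pts[:4],
                               atol=1e-9)


def test_too_many_landmarks_warns(rng):
    with pytest.warns(UserWarning, match="landmarks"):
        fit_tps(random_landmarks(rng, 31))


def test_direction_swap_is_role_swap(rng):
    lm = random_landmarks(rng, 10)
    mov, fix = lm.arrays()
    t_fwd = fit_tps(lm, "moving_to_fixed")
    t_rev = fit_tps(lm, "fixed_to_moving")
    np.testing.assert_allclose(apply_transform(t_fwd, mov), fix, atol=1e-6)
    np.testing.assert_allclose(apply_transform(t_rev, fix), mov, atol=1e-6)


# ------------------------------------------------------------- warping ---

def test_warp_identity_reproduces_image(rng):
    img = Image2D(rng.integers(0, 256, (30, 40)).astype(np.uint8))
    out = warp_image(img, TPSTransform.identity(), (30, 40), "linear")
    np.testing.assert_array_equal(out.pixels, img.pixels)


def test_warp_integer_translation_nearest(rng):
    img = Image2D(rng.integers(0, 256, (20, 20)).astype(np.uint8))
    # pull-back map: output (x,y) samples input (x-5, y), i.e. shift right
    t = TPSTransform(np.array([[-5.0, 1, 0], [0.0, 0, 1]]),
                     np.zeros((0, 2)), np.zeros((0, 2)))
    out = warp_image(img, t, (20, 20), "nearest")
    np.testing.assert_array_equal(out.pixels[:, 5:], img.pixels[:, :15])
    assert (out.pixels[:, :5] == 0).all()


def test_warp_binary_mask_autoswitches_to_nearest(rng):
    mask = np.zeros((20, 20), np.uint8)
    mask[5:15, 5:15] = 255
    t = TPSTransform(np.array([[0.25, 1, 0], [0.0, 0, 1]]),
                     np.zeros((0, 2)), np.zeros((0, 2)))
    with pytest.warns(UserWarning, match="nearest"):
        out = warp_image(Image2D(mask), t, (20, 20), "linear")
    assert set(np.unique(out.pixels)) <= {0, 255}


def test_warped_mask_matches_vertex_warped_polygon(rng):
    """Forward vertex-warp oracle: warping a mask raster through the
    pull-back equals rasterizing the forward-warped polygon."""
    from roit.metrics import dice
    from roit.roi_core import MaskROI, circle, rasterize

    mov = rng.uniform(50, 450, (12, 2))
    fix = mov + rng.normal(0, 12, mov.shape)
    lm = LandmarkSet.from_arrays(mov, fix)
    t_fwd = fit_tps(lm, "moving_to_fixed")
    t_inv = fit_tps(lm, "fixed_to_moving")
    poly = circle(250, 250, 150, n=360)
    mask = rasterize(poly, (512, 512))
    warped_mask = warp_image(Image2D(mask.to_uint8()), t_inv, (512, 512),
                             "nearest")
    vertex_route = rasterize(
        type(poly)(apply_transform(t_fwd, poly.vertices)), (512, 512)
    )
    d = dice(MaskROI(warped_mask.pixels > 127), vertex_route)
    assert d >= 0.99


# ----------------------------------------------------------------- csv ---

def test_landmark_csv_roundtrip(tmp_path, rng):
    pairs = tuple(
        LandmarkPair(f"Pt-{i}", i % 3 != 0,
                     tuple(rng.uniform(0, 100, 2)),
                     tuple(rng.uniform(0, 1000, 2)))
        for i in range(20)
    )
    ls = LandmarkSet(pairs)
    p = tmp_path / "lm.csv"
    write_landmarks_csv(ls, p)
    assert read_landmarks_csv(p) == ls


def test_landmark_csv_malformed_row_names_line(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text('"a","true",1,2,3,4\n"b","true",1,2,3\n')
    with pytest.raises(ValueError, match="line 2"):
        read_landmarks_csv(p)


def test_landmark_csv_inactive_rows_kept_but_not_fitted(tmp_path, rng):
    pts = rng.uniform(0, 100, (4, 2))
    pairs = [LandmarkPair(f"p{i}", True, tuple(pts[i]), tuple(pts[i]))
             for i in range(3)]
    pairs.append(LandmarkPair("off", False, (1.0, 1.0), (99.0, 99.0)))
    p = tmp_path / "lm.csv"
    write_landmarks_csv(LandmarkSet(tuple(pairs)), p)
    back = read_landmarks_csv(p)
    assert len(back) == 4 and len(back.active_pairs) == 3
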