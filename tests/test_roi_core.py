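import struct
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roit.metrics import dice
from roit.roi_core import (
    LineROI,
    MaskROI,
    PolygonROI,
    circle,
    combine,
    fit_spline,
    mask_to_polygon,
    polygon_area,
    rasterize,
    read_csv_roi,
    read_imagej_roi,
    scale_polygon,
    write_csv_roi,
    write_imagej_roi,
)


def square(x0=0.0, y0=0.0, side=1.0, label=""):
    return PolygonROI(
        np.array([[x0, y0], [x0 + side, y0], [x0 + side, y0 + side],
                  [x0, y0 + side]]),
        label=label,
    )


# ---------------------------------------------------------------- types ---

def test_polygon_validation():
    with pytest.raises(ValueError):
        PolygonROI(np.array([[0, 0], [1, 1]]))  # closed needs >= 3
    with pytest.raises(ValueError):
        PolygonROI(np.array([[0, 0], [1, np.nan], [2, 2]]))
    with pytest.raises(ValueError):
        LineROI((1, 1), (1, 1))


# --------------------------------------------------------------- spline ---

def test_spline_interpolates_square_corners():
    sq = square(side=10)
    out = fit_spline(sq, 40)
    assert out.n_vertices == 40
    for v in sq.vertices:
        assert np.min(np.hypot(*(out.vertices - v).T)) < 1e-6


def test_spline_circle_radial_deviation_below_half_percent():
    coarse = circle(100, 100, 50, n=12)
    fine = fit_spline(coarse, 360)
    r = np.hypot(*(fine.vertices - 100).T)
    assert np.abs(r - 50).max() < 0.005 * 50


def test_spline_rejects_too_few_points():
    with pytest.raises(ValueError):
        fit_spline(square(), 3)


# -------------------------------------------------------------- scaling ---

def test_scale_unit_square_quadruples_area():
    out = scale_polygon(square(), 2.0)
    assert out.area() == pytest.approx(4.0)
    assert np.allclose(scale_polygon(square(), 1.0).vertices, square().vertices)
    with pytest.raises(ValueError):
        scale_polygon(square(), 0.0)


@given(a=st.floats(0.1, 20), b=st.floats(0.1, 20))
@settings(max_examples=50, deadline=None)
def test_scale_composition_law_exact(a, b):
    r = PolygonROI(np.array([[0.5, 1.25], [7.0, 2.0], [3.0, 9.0]]))
    lhs = scale_polygon(scale_polygon(r, a), b)
    rhs = scale_polygon(r, a * b)
    # associativity of the two float multiplications holds to the ulp
    np.testing.assert_allclose(lhs.vertices, rhs.vertices, rtol=1e-15)


def test_scale_line_roi():
    ln = scale_polygon(LineROI((1, 2), (3, 4)), 10.0)
    assert ln.p0 == (10, 20) and ln.p1 == (30, 40)


def test_scaled_circle_raster_area_matches_analytic():
    sc = scale_polygon(circle(60, 60, 50, n=360), 3.0)
    area = rasterize(sc, (400, 400)).area_px
    assert area == pytest.approx(np.pi * 150 ** 2, rel=0.01)


def test_vector_scaling_beats_raster_scaling():
    """The premise of carrying ROIs as vectors: scale-then-rasterize is
    closer to the analytic shape than rasterize-then-nearest-zoom."""
    from scipy.ndimage import zoom

    s = 8
    # analytic target: the true circle rasterized directly at the fine grid
    analytic = rasterize(circle(30 * s, 30 * s, 20 * s, n=720), (60 * s, 60 * s))
    small = circle(30, 30, 20, n=360)
    vector_route = rasterize(scale_polygon(small, s), (60 * s, 60 * s))
    raster_route = MaskROI(zoom(rasterize(small, (60, 60)).pixels, s, order=0))
    assert dice(vector_route, analytic) > dice(raster_route, analytic)


# ---------------------------------------------------------- rasterizing ---

def test_rasterize_halfopen_rect_pixel_count():
    r = PolygonROI(np.array([[2, 3], [5, 3], [5, 7], [2, 7]], float))
    m = rasterize(r, (10, 10))
    assert m.area_px == 12
    assert m.pixels[3:7, 2:5].all()


def test_rasterize_outside_frame_and_degenerate():
    far = square(100, 100, 5)
    assert rasterize(far, (20, 20)).area_px == 0
    degenerate = PolygonROI(np.array([[1, 1], [5, 5], [3, 3]], float))
    with pytest.warns(UserWarning, match="degenerate"):
        assert rasterize(degenerate, (10, 10)).area_px == 0


@pytest.mark.parametrize("s", [2.0, 3.5])
def test_raster_area_scales_quadratically(s):
    base = circle(25, 25, 12, n=180)
    n0 = rasterize(base, (50, 50)).area_px
    n1 = rasterize(scale_polygon(base, s), (int(50 * s) + 2, int(50 * s) + 2)).area_px
    assert n1 == pytest.approx(s ** 2 * n0, rel=0.02)


def test_combine_disjoint_overlap_idempotent():
    a = square(1, 1, 10)
    b = square(20, 1, 10)
    assert combine([a, b], (40, 40)).area_px == 200
    assert combine([a, a], (40, 40)).area_px == 100
    c = square(5, 1, 10)  # overlaps a by 6x10
    union = combine([a, c], (40, 40)).area_px
    inter = np.logical_and(rasterize(a, (40, 40)).pixels,
                           rasterize(c, (40, 40)).pixels).sum()
    assert union == 100 + 100 - inter
    with pytest.raises(ValueError):
        combine([], (40, 40))


# ------------------------------------------------------ mask -> polygon ---

def test_single_pixel_traces_to_unit_square():
    m = np.zeros((5, 5), bool)
    m[2, 3] = True
    (poly,) = mask_to_polygon(MaskROI(m), small_px=0)
    assert sorted(map(tuple, poly.vertices.tolist())) == [
        (3.0, 2.0), (3.0, 3.0), (4.0, 2.0), (4.0, 3.0)
    ]


def test_two_blobs_two_polygons_and_empty():
    m = np.zeros((20, 20), bool)
    m[2:5, 2:5] = True
    m[10:14, 10:14] = True
    polys = mask_to_polygon(MaskROI(m), small_px=0)
    assert len(polys) == 2
    assert mask_to_polygon(MaskROI(np.zeros((5, 5), bool))) == []


def test_diagonal_pixels_stay_one_component():
    m = np.zeros((5, 5), bool)
    m[1, 1] = m[2, 2] = True
    polys = mask_to_polygon(MaskROI(m), small_px=0)
    assert len(polys) == 1
    np.testing.assert_array_equal(rasterize(polys[0], (5, 5)).pixels, m)


def test_small_component_warns():
    m = np.zeros((10, 10), bool)
    m[3:5, 3:5] = True
    with pytest.warns(UserWarning, match="small"):
        mask_to_polygon(MaskROI(m))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_smooth_blob_roundtrip_is_exact(seed):
    """rasterize(mask_to_polygon(m)) == m for blobs of ~1e4 px (exceeds the
    Dice >= 0.99 contract)."""
    rng = np.random.default_rng(seed)
    cx, cy = rng.uniform(60, 80, 2)
    blob = circle(cx, cy, rng.uniform(50, 60), n=90)
    m = rasterize(blob, (150, 150))
    assert m.area_px > 7000
    (poly,) = mask_to_polygon(MaskROI(m.pixels), small_px=0)
    back = rasterize(poly, (150, 150))
    assert dice(back, m) == 1.0


# ------------------------------------------------------------ roi files ---

def random_polygon(rng, closed=True, n=None):
    n = n or rng.integers(3, 40)
    verts = rng.uniform(0, 500, (n, 2)).round(3)
    while closed and polygon_area(verts) == 0:
        verts = rng.uniform(0, 500, (n, 2)).round(3)
    return PolygonROI(verts, closed=closed, label=f"r{rng.integers(1e6)}")


def test_imagej_roundtrip_float_precision(tmp_path, rng):
    roi = random_polygon(rng)
    p = tmp_path / "a.roi"
    write_imagej_roi(roi, p)
    (back,) = read_imagej_roi(p)
    # coordinates are stored as 32-bit floats in the file
    np.testing.assert_allclose(back.vertices, roi.vertices, atol=1e-3)
    assert back.closed


def test_imagej_integer_vertices_roundtrip_exact(tmp_path):
    roi = PolygonROI(np.array([[10, 20], [50, 22], [30, 70]], float), label="p")
    p = tmp_path / "a.roi"
    write_imagej_roi(roi, p)
    np.testing.assert_array_equal(read_imagej_roi(p)[0].vertices, roi.vertices)


def test_imagej_zip_container_many(tmp_path, rng):
    rois = [random_polygon(rng) for _ in range(10)]
    rois += [LineROI(tuple(rng.uniform(0, 100, 2)), tuple(rng.uniform(0, 100, 2)))]
    p = tmp_path / "set.zip"
    write_imagej_roi(rois, p)
    back = read_imagej_roi(p)
    assert len(back) == len(rois)
    polys = {b.label: b for b in back if isinstance(b, PolygonROI)}
    assert set(polys) == {r.label for r in rois[:10]}
    for orig in rois[:10]:
        np.testing.assert_allclose(polys[orig.label].vertices, orig.vertices,
                                   atol=1e-3)


def test_imagej_header_bytes_follow_published_layout(tmp_path):
    roi = PolygonROI(np.array([[10.5, 20.25], [50, 22], [30, 70]]), label="p")
    p = tmp_path / "a.roi"
    write_imagej_roi(roi, p)
    data = p.read_bytes()
    assert data[:4] == b"Iout"
    assert data[6] == 0  # polygon type
    top, left, bottom, right, n = struct.unpack_from(">hhhhh", data, 8)
    assert (top, left) == (20, 10) and n == 3
    options = struct.unpack_from(">h", data, 50)[0]
    assert options & 128  # sub-pixel resolution flag
    fx = np.frombuffer(data, ">f4", n, 64 + 4 * n)
    np.testing.assert_allclose(fx, [10.5, 50, 30])


def test_imagej_bad_magic_and_unsupported(tmp_path):
    bad = tmp_path / "bad.roi"
    bad.write_bytes(b"XXXX" + b"\0" * 60)
    with pytest.raises(ValueError, match="Iout"):
        read_imagej_roi(bad)
    pt = bytearray(b"Iout" + b"\0" * 60)
    pt[5] = 228
    pt[6] = 10  # point ROI
    f = tmp_path / "pt.roi"
    f.write_bytes(bytes(pt))
    with pytest.raises(ValueError, match="point"):
        read_imagej_roi(f)


def test_imagej_rect_decodes_to_four_vertices(tmp_path):
    hdr = bytearray(64)
    struct.pack_into(">4sh", hdr, 0, b"Iout", 228)
    hdr[6] = 1  # rectangle
    struct.pack_into(">hhhh", hdr, 8, 3, 2, 9, 7)  # top,left,bottom,right
    f = tmp_path / "rect.roi"
    f.write_bytes(bytes(hdr))
    (rect,) = read_imagej_roi(f)
    assert rect.n_vertices == 4
    assert rect.vertices[:, 0].min() == 2 and rect.vertices[:, 0].max() == 7
    assert rect.vertices[:, 1].min() == 3 and rect.vertices[:, 1].max() == 9


def test_imagej_oval_discretized(tmp_path):
    hdr = bytearray(64)
    struct.pack_into(">4sh", hdr, 0, b"Iout", 228)
    hdr[6] = 2  # oval
    struct.pack_into(">hhhh", hdr, 8, 0, 0, 10, 20)
    f = tmp_path / "oval.roi"
    f.write_bytes(bytes(hdr))
    (oval,) = read_imagej_roi(f)
    assert oval.n_vertices >= 72
    assert oval.vertices[:, 0].max() == pytest.approx(20, abs=0.01)


def test_csv_roundtrip(tmp_path, rng):
    roi = random_polygon(rng)
    p = tmp_path / "r.csv"
    write_csv_roi(roi, p)
    assert p.read_text().splitlines()[0] == "x,y"
    np.testing.assert_allclose(read_csv_roi(p).vertices, roi.vertices,
                               atol=1e-6)
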