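"""Vector ROI machinery.

ROIs travel through the transfer pipeline in two representations:

* a *vector* form (:class:`PolygonROI` / :class:`LineROI`) — an ordered list
  of continuous pixel coordinates.  Scaling a vector ROI is exact: every
  coordinate is multiplied, no raster is touched, so a curved outline keeps
  its shape with no "stepped" aliasing no matter how large the scale factor
  between the MR and histology frames (typically around 10x);
* a *raster* form (:class:`MaskROI`) — a binary mask, used to encode ROIs as
  color channels of the composite image that rides through registration.

This module provides conversion in both directions, spline smoothing,
ROI union, and I/O for the ImageJ ``.roi`` binary format (and ``.zip``
containers of them) plus plain CSV vertex lists.
"""

from __future__ import annotations

import io
import os
import struct
import warnings
import zipfile
from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import CubicSpline
from skimage import measure as skmeasure

__all__ = [
    "PolygonROI",
    "LineROI",
    "MaskROI",
    "circle",
    "fit_spline",
    "combine",
    "scale_polygon",
    "rasterize",
    "mask_to_polygon",
    "polygon_area",
    "read_imagej_roi",
    "write_imagej_roi",
    "read_csv_roi",
    "write_csv_roi",
    "SMALL_ROI_PX",
]

#: Components smaller than this (in pixels) trigger a reliability warning:
#: very small regions do not survive raster->vector->raster transport well.
SMALL_ROI_PX = 50


@dataclass(frozen=True)
class PolygonROI:
    """Ordered vertices in continuous pixel coordinates.

    ``closed=True`` means the last vertex connects back to the first
    (a region); ``closed=False`` is an open polyline.
    """

    vertices: np.ndarray  # (N, 2) float, columns (x, y)
    closed: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"vertices must be (N, 2), got {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("vertices contain NaN/inf")
        if self.closed and len(v) < 3:
            raise ValueError("a closed polygon needs at least 3 vertices")
        if len(v) < 2:
            raise ValueError("a polyline needs at least 2 vertices")
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def area(self) -> float:
        """Absolute polygon (shoelace) area; 0 for open polylines."""
        return abs(polygon_area(self.vertices)) if self.closed else 0.0


@dataclass(frozen=True)
class LineROI:
    """Straight-line selection, used to mark the vertical slice dimension."""

    p0: Tuple[float, float]
    p1: Tuple[float, float]
    label: str = ""

    def __post_init__(self) -> None:
        if tuple(self.p0) == tuple(self.p1):
            raise ValueError("line endpoints must differ")

    @property
    def length(self) -> float:
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))


@dataclass(frozen=True)
class MaskROI:
    """Binary raster ROI."""

    pixels: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be 2D")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def to_uint8(self) -> np.ndarray:
        """{0, 255} raster, the encoding used in composite color channels."""
        return self.pixels.astype(np.uint8) * 255


def polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area (positive for clockwise loops in y-down coords)."""
    v = np.asarray(vertices, dtype=np.float64)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def circle(cx: float, cy: float, r: float, n: int = 72, label: str = "") -> PolygonROI:
    """Regular ``n``-gon approximating a circle — the standard-size round
    ROI used for lesion / contralateral intensity measurements."""
    if r <= 0:
        raise ValueError("radius must be positive")
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    verts = np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])
    return PolygonROI(verts, closed=True, label=label)


# ---------------------------------------------------------------------------
# spline fitting
# ---------------------------------------------------------------------------

def fit_spline(roi: PolygonROI, n_points: int) -> PolygonROI:
    """Smooth a closed polygon with a periodic cubic spline.

    The spline interpolates every input vertex; the output is resampled at
    ``n_points`` positions approximately uniform in arc length, anchored so
    that every original vertex is among the output points.
    """
    if not roi.closed:
        raise ValueError("fit_spline requires a closed polygon")
    m = roi.n_vertices
    if n_points < m:
        raise ValueError(f"n_points ({n_points}) must be >= vertex count ({m})")
    pts = np.vstack([roi.vertices, roi.vertices[:1]])  # close the loop
    chord = np.hypot(*np.diff(pts, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    spl = CubicSpline(t, pts, bc_type="periodic")

    # arc length of each spline segment, by dense evaluation
    dense_per_seg = 64
    seg_lengths = np.empty(m)
    seg_dense_t = []
    seg_dense_s = []
    for i in range(m):
        tt = np.linspace(t[i], t[i + 1], dense_per_seg + 1)
        pp = spl(tt)
        ds = np.hypot(*np.diff(pp, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(ds)])
        seg_lengths[i] = s[-1]
        seg_dense_t.append(tt)
        seg_dense_s.append(s)

    # distribute the n_points - m extra samples over segments by arc length
    extra = n_points - m
    quota = seg_lengths / seg_lengths.sum() * extra
    counts = np.floor(quota).astype(int)
    remainder = extra - counts.sum()
    if remainder > 0:
        order = np.argsort(-(quota - counts))
        counts[order[:remainder]] += 1

    out = []
    for i in range(m):
        out.append(roi.vertices[i])  # exact knot
        k = counts[i]
        if k:
            targets = seg_lengths[i] * (np.arange(1, k + 1) / (k + 1))
            tt = np.interp(targets, seg_dense_s[i], seg_dense_t[i])
            out.extend(spl(tt))
    return PolygonROI(np.asarray(out), closed=True, label=roi.label)


# ---------------------------------------------------------------------------
# scaling, rasterization, union
# ---------------------------------------------------------------------------

def scale_polygon(roi: Union[PolygonROI, LineROI], s: float):
    """Multiply every coordinate by ``s`` about the frame origin.

    Purely a vector operation — no raster is created, so arbitrarily large
    scale factors introduce no aliasing and scaling composes exactly:
    ``scale(scale(R, a), b) == scale(R, a*b)``.
    """
    if s <= 0:
        raise ValueError("scale factor must be positive")
    if isinstance(roi, LineROI):
        return LineROI(
            (roi.p0[0] * s, roi.p0[1] * s), (roi.p1[0] * s, roi.p1[1] * s), roi.label
        )
    return replace(roi, vertices=roi.vertices * s)


def rasterize(roi: PolygonROI, shape: Tuple[int, int]) -> MaskROI:
    """Rasterize a closed polygon: a pixel is set iff its center lies inside
    (nonzero winding rule), clipped to ``shape``.

    Scanline implementation: a pixel row at y = i + 0.5 collects the signed
    x-crossings of all non-horizontal edges (an edge counts for the rows
    with y_low <= i+0.5 < y_high, signed by its direction); between
    consecutive sorted crossings the winding number is constant, and the
    pixel centers in intervals of nonzero winding are filled.  Work is
    proportional to the number of edge/row crossings, so many-vertex traced
    outlines rasterize quickly.
    """
    if not roi.closed:
        raise ValueError("only closed polygons can be rasterized")
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    if roi.area() == 0.0:
        warnings.warn(f"degenerate zero-area polygon {roi.label!r}: empty mask")
        return MaskROI(mask)
    v = roi.vertices
    rows: List[list] = [[] for _ in range(h)]
    x2s = np.roll(v[:, 0], -1)
    y2s = np.roll(v[:, 1], -1)
    for ex1, ey1, ex2, ey2 in zip(v[:, 0], v[:, 1], x2s, y2s):
        if ey1 == ey2:
            continue  # horizontal edges never cross a row center line
        sign = 1 if ey2 > ey1 else -1
        ylo, yhi = (ey1, ey2) if sign > 0 else (ey2, ey1)
        i0 = max(int(np.ceil(ylo - 0.5)), 0)
        i1 = min(int(np.ceil(yhi - 0.5)) - 1, h - 1)
        if i1 < i0:
            continue
        yc = np.arange(i0, i1 + 1) + 0.5
        xs = ex1 + (yc - ey1) * (ex2 - ex1) / (ey2 - ey1)
        for i, xc in zip(range(i0, i1 + 1), xs):
            rows[i].append((xc, sign))
    for i, crossings in enumerate(rows):
        if not crossings:
            continue
        crossings.sort()
        winding = 0
        for (xa, sa), (xb, _sb) in zip(crossings, crossings[1:]):
            winding += sa
            if winding != 0:
                j0 = max(int(np.ceil(xa - 0.5)), 0)
                j1 = min(int(np.ceil(xb - 0.5)) - 1, w - 1)
                if j1 >= j0:
                    mask[i, j0 : j1 + 1] = True
    return MaskROI(mask)


def combine(rois: Sequence[PolygonROI], shape: Tuple[int, int]) -> MaskROI:
    """Union (logical OR) of rasterized ROIs on a shared raster — the
    equivalent of combining several selections into one before transfer."""
    if len(rois) == 0:
        raise ValueError("combine needs at least one ROI")
    out = np.zeros(shape, dtype=bool)
    for roi in rois:
        out |= rasterize(roi, shape).pixels
    return MaskROI(out)


# ---------------------------------------------------------------------------
# mask -> polygon (crack-boundary tracing)
# ---------------------------------------------------------------------------

# Directed boundary edges run clockwise (screen coordinates, y down) around
# each foreground region, interior on the right of travel.

def _trace_component(comp: np.ndarray) -> np.ndarray:
    """Trace the outer pixel-edge boundary of one hole-free 8-connected
    component; returns (N, 2) corner coordinates (x, y)."""
    fg = comp
    pad = np.pad(fg, 1)
    no_up = fg & ~pad[:-2, 1:-1]
    no_down = fg & ~pad[2:, 1:-1]
    no_left = fg & ~pad[1:-1, :-2]
    no_right = fg & ~pad[1:-1, 2:]

    edges: dict = {}

    def add(start, end):
        edges.setdefault(start, []).append(end)

    for (arr, mk) in (
        (no_up, lambda i, j: ((j, i), (j + 1, i))),          # top, heading +x
        (no_right, lambda i, j: ((j + 1, i), (j + 1, i + 1))),  # right, +y
        (no_down, lambda i, j: ((j + 1, i + 1), (j, i + 1))),   # bottom, -x
        (no_left, lambda i, j: ((j, i + 1), (j, i))),           # left, -y
    ):
        ii, jj = np.nonzero(arr)
        for i, j in zip(ii.tolist(), jj.tolist()):
            add(*mk(i, j))

    # start at the top-left corner of the first (row-major) foreground pixel;
    # that vertex can never be a self-touching corner, so the walk terminates
    # exactly when it returns there
    i0, j0 = np.argwhere(fg)[0]
    start = (int(j0), int(i0))
    loop = [start]
    cur = start
    prev_dir = None
    while True:
        cands = edges[cur]
        if len(cands) == 1 or prev_dir is None:
            nxt = cands[0]
        else:
            # at a self-touching corner prefer the screen-left turn, which
            # carries the trace across the diagonal and keeps 8-connected
            # components as a single outline
            dx, dy = prev_dir
            want = (cur[0] + dy, cur[1] - dx)
            nxt = want if want in cands else cands[0]
        cands.remove(nxt)
        if not cands:
            del edges[cur]
        prev_dir = (nxt[0] - cur[0], nxt[1] - cur[1])
        if nxt == start:
            break
        loop.append(nxt)
        cur = nxt
    return _drop_collinear(np.asarray(loop, dtype=np.float64))


def _drop_collinear(verts: np.ndarray) -> np.ndarray:
    """Remove vertices interior to straight axis-aligned runs."""
    prev_d = verts - np.roll(verts, 1, axis=0)
    next_d = np.roll(verts, -1, axis=0) - verts
    # all steps are axis-aligned: a vertex is redundant iff direction repeats
    keep = ~((prev_d[:, 0] == next_d[:, 0]) & (prev_d[:, 1] == next_d[:, 1]))
    out = verts[keep]
    return out if len(out) >= 3 else verts


def mask_to_polygon(mask: MaskROI, small_px: int = SMALL_ROI_PX) -> List[PolygonROI]:
    """Recover vector outlines from a binary mask.

    One closed polygon is traced along the pixel-edge boundary of each
    8-connected component, so rasterizing the result reproduces the mask
    exactly (interior holes are filled; donut regions are out of scope).
    Components smaller than ``small_px`` are kept but flagged with a
    warning — very small ROIs transfer unreliably.
    """
    m = mask.pixels
    if not m.any():
        return []
    labels, n = skmeasure.label(m, connectivity=2, return_num=True)
    polys: List[PolygonROI] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        area = int(comp.sum())
        if area < small_px:
            warnings.warn(
                f"component {lab} has only {area} px (< {small_px}); "
                "small ROIs may not survive transfer"
            )
        ys, xs = np.nonzero(comp)
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        sub = ndi.binary_fill_holes(comp[y0:y1, x0:x1])
        verts = _trace_component(sub)
        verts += [x0, y0]
        polys.append(PolygonROI(verts, closed=True, label=f"region-{lab}"))
    return polys


# ---------------------------------------------------------------------------
# ImageJ .roi binary format
# ---------------------------------------------------------------------------
# 64-byte big-endian header starting with the magic "Iout", then integer
# vertex coordinates relative to the bounding box, then (when the sub-pixel
# option bit is set) absolute float coordinates.

_MAGIC = b"Iout"
_VERSION = 228
_OPT_SUB_PIXEL = 128

_TYPE_POLYGON = 0
_TYPE_RECT = 1
_TYPE_OVAL = 2
_TYPE_LINE = 3
_TYPE_FREELINE = 4
_TYPE_POLYLINE = 5
_TYPE_FREEHAND = 7
_TYPE_TRACED = 8

_TYPE_NAMES = {6: "no-roi", 9: "angle", 10: "point/multipoint"}

RoiLike = Union[PolygonROI, LineROI]


def _encode_roi(roi: RoiLike) -> bytes:
    if isinstance(roi, LineROI):
        (x0, y0), (x1, y1) = roi.p0, roi.p1
        hdr = bytearray(64)
        struct.pack_into(">4sh", hdr, 0, _MAGIC, _VERSION)
        hdr[6] = _TYPE_LINE
        struct.pack_into(
            ">hhhh", hdr, 8,
            int(np.floor(min(y0, y1))), int(np.floor(min(x0, x1))),
            int(np.ceil(max(y0, y1))), int(np.ceil(max(x0, x1))),
        )
        struct.pack_into(">ffff", hdr, 18, x0, y0, x1, y1)
        struct.pack_into(">h", hdr, 50, _OPT_SUB_PIXEL)
        return bytes(hdr)

    v = roi.vertices
    n = len(v)
    left = int(np.floor(v[:, 0].min()))
    top = int(np.floor(v[:, 1].min()))
    right = int(np.ceil(v[:, 0].max()))
    bottom = int(np.ceil(v[:, 1].max()))
    hdr = bytearray(64)
    struct.pack_into(">4sh", hdr, 0, _MAGIC, _VERSION)
    hdr[6] = _TYPE_POLYGON if roi.closed else _TYPE_POLYLINE
    struct.pack_into(">hhhhh", hdr, 8, top, left, bottom, right, n)
    struct.pack_into(">h", hdr, 50, _OPT_SUB_PIXEL)
    buf = io.BytesIO()
    buf.write(bytes(hdr))
    ix = np.clip(np.round(v[:, 0]) - left, -32768, 32767).astype(">i2")
    iy = np.clip(np.round(v[:, 1]) - top, -32768, 32767).astype(">i2")
    buf.write(ix.tobytes())
    buf.write(iy.tobytes())
    buf.write(v[:, 0].astype(">f4").tobytes())
    buf.write(v[:, 1].astype(">f4").tobytes())
    return buf.getvalue()


def _decode_roi(data: bytes, name: str = "") -> RoiLike:
    if len(data) < 64 or data[:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI file (missing 'Iout' magic bytes)")
    version = struct.unpack_from(">h", data, 4)[0]
    rtype = data[6]
    top, left, bottom, right, n = struct.unpack_from(">hhhhh", data, 8)
    options = struct.unpack_from(">h", data, 50)[0]
    sub_pixel = bool(options & _OPT_SUB_PIXEL) and version >= 222

    if rtype == _TYPE_LINE:
        x0, y0, x1, y1 = struct.unpack_from(">ffff", data, 18)
        return LineROI((x0, y0), (x1, y1), label=name)
    if rtype == _TYPE_RECT:
        verts = np.array(
            [[left, top], [right, top], [right, bottom], [left, bottom]], float
        )
        return PolygonROI(verts, closed=True, label=name)
    if rtype == _TYPE_OVAL:
        cx, cy = (left + right) / 2.0, (top + bottom) / 2.0
        rx, ry = (right - left) / 2.0, (bottom - top) / 2.0
        t = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        verts = np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])
        return PolygonROI(verts, closed=True, label=name)
    if rtype in (_TYPE_POLYGON, _TYPE_FREEHAND, _TYPE_TRACED,
                 _TYPE_POLYLINE, _TYPE_FREELINE):
        closed = rtype in (_TYPE_POLYGON, _TYPE_FREEHAND, _TYPE_TRACED)
        if sub_pixel:
            off = 64 + 4 * n
            fx = np.frombuffer(data, ">f4", n, off).astype(np.float64)
            fy = np.frombuffer(data, ">f4", n, off + 4 * n).astype(np.float64)
            verts = np.column_stack([fx, fy])
        else:
            ix = np.frombuffer(data, ">i2", n, 64).astype(np.float64)
            iy = np.frombuffer(data, ">i2", n, 64 + 2 * n).astype(np.float64)
            verts = np.column_stack([ix + left, iy + top])
        return PolygonROI(verts, closed=closed, label=name)
    kind = _TYPE_NAMES.get(rtype, f"type {rtype}")
    raise ValueError(f"unsupported ImageJ ROI subtype: {kind}")


def write_imagej_roi(rois: Union[RoiLike, Sequence[RoiLike]], path) -> None:
    """Write one ROI as ``.roi`` or several as a ``.zip`` container."""
    path = os.fspath(path)
    if path.lower().endswith(".zip"):
        rois = [rois] if isinstance(rois, (PolygonROI, LineROI)) else list(rois)
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            for k, roi in enumerate(rois):
                name = roi.label or f"roi-{k:04d}"
                zf.writestr(f"{name}.roi", _encode_roi(roi))
    else:
        if not isinstance(rois, (PolygonROI, LineROI)):
            if len(rois) != 1:
                raise ValueError("a .roi file holds a single ROI; use .zip")
            rois = rois[0]
        with open(path, "wb") as fh:
            fh.write(_encode_roi(rois))


def read_imagej_roi(path) -> List[RoiLike]:
    """Read a ``.roi`` file or a ``.zip`` of them; always returns a list."""
    path = os.fspath(path)
    if path.lower().endswith(".zip") or zipfile.is_zipfile(path):
        out = []
        with zipfile.ZipFile(path) as zf:
            for info in zf.infolist():
                name = os.path.splitext(os.path.basename(info.filename))[0]
                out.append(_decode_roi(zf.read(info), name))
        return out
    with open(path, "rb") as fh:
        data = fh.read()
    name = os.path.splitext(os.path.basename(path))[0]
    return [_decode_roi(data, name)]


def write_csv_roi(roi: PolygonROI, path) -> None:
    """Plain-text escape hatch: ``x,y`` header plus one vertex per row."""
    np.savetxt(path, roi.vertices, delimiter=",", header="x,y", comments="",
               fmt="%.9g")


def read_csv_roi(path, closed: bool = True, label: str = "") -> PolygonROI:
    verts = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return PolygonROI(verts, closed=closed, label=label)
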