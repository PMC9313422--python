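"""Synthetic MRI/histology phantom pairs with known ground truth.

Real validation data for ROI transfer (in-vivo rat MR slices and matched
stained cryosections) cannot ship with a software package, so every stage of
the pipeline is exercised on phantoms that emulate the geometry of a coronal
rodent brain slice:

* a low-resolution grayscale "MRI": an elliptical brain (width:height about
  1.85, inside the range observed on in-vivo MR slices), a bright C-shaped
  white-matter band standing in for the corpus callosum (CC), bilateral
  "caudoputamen" discs, and a hypointense lesion disc on one side;
* a high-resolution RGB "histology" counterpart: the same anatomy scaled up
  (default 10x), stretched mediolaterally (default 1.15x — cut sections
  spread sideways on the slide relative to in-vivo anatomy), smoothly warped,
  and rendered as a transmitted-light micrograph whose red channel is
  attenuated where a blue myelin stain would bind (Beer–Lambert, so a
  programmed lesion contrast appears as the same relative drop in optical
  density that it is in the MR intensity).

The deforming map is itself a thin-plate spline on a coarse jittered grid —
deliberately the same family the registration fits, so that with exact
landmarks the pipeline can in principle recover the deformation and any
degradation is attributable to landmark count and jitter.  A B-spline
displacement family is available for out-of-family stress tests.

Ground-truth ROIs on the histology side are the exact vertex-wise images of
the MRI-side ROIs under scaling followed by the ground-truth warp, and the
landmark sites satisfy the map exactly; everything is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .imagio import Image2D
from .registration import LandmarkSet, TPSTransform, apply_transform, fit_tps
from .roi_core import LineROI, PolygonROI, circle
from .pipeline import ScaleSpec

__all__ = [
    "PhantomParams",
    "PhantomPair",
    "generate_phantom_pair",
    "landmark_subsample",
    "measure_percent_changes",
]

# reference geometry on a 180x180 MR frame (continuous pixel coordinates)
_REF = {
    "frame": 180.0,
    "brain_center": (90.0, 90.0),
    "brain_semi": (75.0, 40.0),          # width 150, height 80: ratio 1.875
    "cc_center": (90.0, 120.0),
    "cc_radius": 50.0,
    "cc_half_thickness": 4.0,
    "cc_angles_deg": (-145.0, -35.0),    # upper arc (y points down)
    "caud_centers": ((126.0, 110.0), (54.0, 110.0)),  # (lesion side, contra)
    "caud_radius": 14.0,
    "lesion_render_radius": 12.0,
    "measure_radius": 9.0,
    "line_x": 90.0,
    "line_y": (50.0, 130.0),             # the vertical slice-size line
}

# rendering constants
_MRI_BG, _MRI_TISSUE, _MRI_CAUD, _MRI_CC = 10.0, 120.0, 140.0, 190.0
_OD_TISSUE, _OD_CAUD, _OD_CC = 0.12, 0.35, 0.55
_HIST_WHITE = 235.0
# channel-wise absorbance factors of the blue stain (red absorbs most)
_CHANNEL_ABS = (1.0, 0.7, 0.25)


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters; the defaults are the reference conditions
    every validation experiment in this package runs under."""

    mri_shape: Tuple[int, int] = (180, 180)
    scale: float = 10.0
    lateral_stretch: float = 1.15
    warp_amplitude_px: float = 15.0   # at histology scale
    warp_grid: int = 5                # control grid is warp_grid x warp_grid
    noise_sd: float = 2.0             # additive Gaussian, 8-bit units
    lesion_contrast: float = 0.3      # fractional signal/stain loss
    seed: int = 0
    warp_family: str = "tps"          # or "bspline" (out-of-family)

    def __post_init__(self) -> None:
        if self.scale <= 1:
            raise ValueError("scale must be > 1 (histology is the fine frame)")
        if self.lateral_stretch < 1:
            raise ValueError("lateral_stretch must be >= 1")
        if self.warp_amplitude_px < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0.0 <= self.lesion_contrast <= 1.0:
            raise ValueError("lesion_contrast must be in [0, 1]")
        if self.warp_family not in ("tps", "bspline"):
            raise ValueError("warp_family must be 'tps' or 'bspline'")


class BSplineWarp:
    """Smooth displacement-field map (bicubic interpolation of a coarse
    displacement grid) — a deformation *outside* the thin-plate family."""

    def __init__(self, grid_x, grid_y, disp_x, disp_y, stretch):
        self._fx = RectBivariateSpline(grid_y, grid_x, disp_x, kx=3, ky=3)
        self._fy = RectBivariateSpline(grid_y, grid_x, disp_y, kx=3, ky=3)
        self.stretch = stretch

    def __call__(self, points):
        pts = np.atleast_2d(np.asarray(points, float))
        out = np.empty_like(pts)
        out[:, 0] = pts[:, 0] * self.stretch + self._fx(
            pts[:, 1], pts[:, 0], grid=False
        )
        out[:, 1] = pts[:, 1] + self._fy(pts[:, 1], pts[:, 0], grid=False)
        return out


@dataclass(frozen=True)
class PhantomPair:
    """A synthetic MRI/histology pair with complete ground truth."""

    mri: Image2D
    histology: Image2D
    gt_forward: object               # scaled-MRI -> histology map (callable)
    gt_rois_mri: Dict[str, PolygonROI]
    gt_rois_hist: Dict[str, PolygonROI]
    landmarks: LandmarkSet           # 20 exact pairs (scaled-MRI vs hist)
    lines: ScaleSpec                 # source: MRI frame, target: histology
    landmark_sites: Tuple[np.ndarray, np.ndarray]  # all (moving, fixed) sites
    params: PhantomParams

    @property
    def background_roi_hist(self) -> PolygonROI:
        """A blank-glass circle near the histology corner, for OD
        background correction."""
        g = min(self.mri.shape) / _REF["frame"] * self.params.scale
        r = 4.0 * g
        return circle(1.5 * r, 1.5 * r, r, label="background")


def _geometry(shape: Tuple[int, int]) -> Dict[str, object]:
    """Reference geometry scaled uniformly to the requested MR frame."""
    g = min(shape) / _REF["frame"]
    geo = {
        "brain_center": tuple(np.multiply(_REF["brain_center"], g)),
        "brain_semi": tuple(np.multiply(_REF["brain_semi"], g)),
        "cc_center": tuple(np.multiply(_REF["cc_center"], g)),
        "cc_radius": _REF["cc_radius"] * g,
        "cc_half_thickness": _REF["cc_half_thickness"] * g,
        "cc_angles": tuple(np.deg2rad(_REF["cc_angles_deg"])),
        "caud_centers": tuple(
            tuple(np.multiply(c, g)) for c in _REF["caud_centers"]
        ),
        "caud_radius": _REF["caud_radius"] * g,
        "lesion_render_radius": _REF["lesion_render_radius"] * g,
        "measure_radius": _REF["measure_radius"] * g,
        "line": (
            (_REF["line_x"] * g, _REF["line_y"][0] * g),
            (_REF["line_x"] * g, _REF["line_y"][1] * g),
        ),
    }
    return geo


def _region_fields(points: np.ndarray, geo, lesion_contrast: float):
    """Evaluate (mri_intensity, optical_density) at continuous MRI-frame
    points, from the analytic region definitions."""
    x, y = points[:, 0], points[:, 1]
    bc, (ax_, ay_) = geo["brain_center"], geo["brain_semi"]
    in_brain = ((x - bc[0]) / ax_) ** 2 + ((y - bc[1]) / ay_) ** 2 <= 1.0

    cc, rr = geo["cc_center"], geo["cc_radius"]
    d_cc = np.hypot(x - cc[0], y - cc[1])
    ang = np.arctan2(y - cc[1], x - cc[0])
    a0, a1 = geo["cc_angles"]
    in_cc = (
        (np.abs(d_cc - rr) <= geo["cc_half_thickness"])
        & (ang >= a0) & (ang <= a1)
    )

    (lc, cc_side) = geo["caud_centers"]
    d_les_caud = np.hypot(x - lc[0], y - lc[1])
    d_con_caud = np.hypot(x - cc_side[0], y - cc_side[1])
    in_caud = (d_les_caud <= geo["caud_radius"]) | (
        d_con_caud <= geo["caud_radius"]
    )
    in_lesion = d_les_caud <= geo["lesion_render_radius"]

    inten = np.full(len(x), _MRI_BG)
    od = np.zeros(len(x))
    inten[in_brain] = _MRI_TISSUE
    od[in_brain] = _OD_TISSUE
    inten[in_caud] = _MRI_CAUD
    od[in_caud] = _OD_CAUD
    inten[in_cc] = _MRI_CC
    od[in_cc] = _OD_CC
    f = 1.0 - lesion_contrast
    inten[in_lesion] *= f
    od[in_lesion] *= f
    inten[~in_brain] = _MRI_BG
    od[~in_brain] = 0.0
    return inten, od


def _gt_rois_mri(geo) -> Dict[str, PolygonROI]:
    t = np.linspace(0, 2 * np.pi, 144, endpoint=False)
    bc, (ax_, ay_) = geo["brain_center"], geo["brain_semi"]
    brain = PolygonROI(
        np.column_stack([bc[0] + ax_ * np.cos(t), bc[1] + ay_ * np.sin(t)]),
        label="brain",
    )
    a = np.linspace(*geo["cc_angles"], 60)
    cc, rr, ht = geo["cc_center"], geo["cc_radius"], geo["cc_half_thickness"]
    outer = np.column_stack(
        [cc[0] + (rr + ht) * np.cos(a), cc[1] + (rr + ht) * np.sin(a)]
    )
    inner = np.column_stack(
        [cc[0] + (rr - ht) * np.cos(a[::-1]), cc[1] + (rr - ht) * np.sin(a[::-1])]
    )
    cc_band = PolygonROI(np.vstack([outer, inner]), label="cc")
    (lc, ctr) = geo["caud_centers"]
    r = geo["measure_radius"]
    return {
        "brain": brain,
        "cc": cc_band,
        "lesion": circle(*lc, r, label="lesion"),
        "contralateral": circle(*ctr, r, label="contralateral"),
    }


def _landmark_sites(geo) -> np.ndarray:
    """30 well-identifiable sites in MRI coordinates: 18 on the brain
    outline, 8 along the CC mid-line, 2 caudoputamen centers, 2 midline
    interior points."""
    bc, (ax_, ay_) = geo["brain_center"], geo["brain_semi"]
    t = np.linspace(0, 2 * np.pi, 18, endpoint=False)
    outline = np.column_stack(
        [bc[0] + ax_ * np.cos(t), bc[1] + ay_ * np.sin(t)]
    )
    a = np.linspace(*geo["cc_angles"], 8)
    cc, rr = geo["cc_center"], geo["cc_radius"]
    cc_sites = np.column_stack([cc[0] + rr * np.cos(a), cc[1] + rr * np.sin(a)])
    extra = np.array(
        [geo["caud_centers"][0], geo["caud_centers"][1],
         (bc[0], bc[1] - 0.5 * ay_), (bc[0], bc[1] + 0.5 * ay_)]
    )
    return np.vstack([outline, cc_sites, extra])


def _make_gt_warp(params: PhantomParams, scaled_shape, rng):
    """Ground-truth scaled-MRI -> histology map: lateral stretch plus a
    smooth random deformation anchored on a coarse control grid."""
    hs, ws = scaled_shape
    n = params.warp_grid
    gx = np.linspace(0.0, ws, n)
    gy = np.linspace(0.0, hs, n)
    gxx, gyy = np.meshgrid(gx, gy)
    src = np.column_stack([gxx.ravel(), gyy.ravel()])
    disp = rng.normal(0.0, params.warp_amplitude_px, size=(n * n, 2))
    if params.warp_family == "bspline":
        return BSplineWarp(
            gx, gy,
            disp[:, 0].reshape(n, n), disp[:, 1].reshape(n, n),
            params.lateral_stretch,
        )
    dst = np.column_stack(
        [src[:, 0] * params.lateral_stretch + disp[:, 0],
         src[:, 1] + disp[:, 1]]
    )
    lm = LandmarkSet.from_arrays(src, dst)
    with np.errstate(all="ignore"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # grid may exceed the soft landmark cap
            return fit_tps(lm, "moving_to_fixed", 0.0)


def _warp_points(gt, points):
    if isinstance(gt, TPSTransform):
        return apply_transform(gt, points)
    return gt(points)


def _fit_render_inverse(gt, scaled_shape, rng):
    """Approximate histology -> scaled-MRI map for rendering, fitted on a
    dense grid of forward correspondences."""
    hs, ws = scaled_shape
    n = 9
    gx = np.linspace(0.0, ws, n)
    gy = np.linspace(0.0, hs, n)
    gxx, gyy = np.meshgrid(gx, gy)
    src = np.column_stack([gxx.ravel(), gyy.ravel()])
    dst = _warp_points(gt, src)
    lm = LandmarkSet.from_arrays(dst, src)  # reversed roles
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        return fit_tps(lm, "moving_to_fixed", 0.0)


def generate_phantom_pair(
    params: PhantomParams = PhantomParams(),
    render_histology: bool = True,
) -> PhantomPair:
    """Generate one deterministic phantom pair from ``params.seed``.

    ``render_histology=False`` leaves the histology raster blank white —
    a fast path for geometry-only experiments (ROI transport, landmarks);
    all geometry, noise draws and ground truth are bit-identical to the
    rendered pair because the histology noise is drawn last.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.mri_shape
    geo = _geometry(params.mri_shape)
    s = params.scale

    # --- MRI raster -------------------------------------------------------
    xs = np.arange(w) + 0.5
    ys = np.arange(h) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inten, _ = _region_fields(pts, geo, params.lesion_contrast)
    mri_px = inten + rng.normal(0.0, params.noise_sd, size=inten.shape)
    mri = Image2D(
        np.clip(np.round(mri_px.reshape(h, w)), 0, 255).astype(np.uint8),
        pixel_size_mm=(0.2, 0.2),
    )

    # --- ground-truth warp ------------------------------------------------
    scaled_shape = (int(round(h * s)), int(round(w * s)))
    hist_shape = (
        scaled_shape[0],
        int(round(scaled_shape[1] * params.lateral_stretch)),
    )
    gt = _make_gt_warp(params, scaled_shape, rng)

    # --- ground-truth ROIs ------------------------------------------------
    rois_mri = _gt_rois_mri(geo)
    rois_hist = {}
    for name, roi in rois_mri.items():
        hv = _warp_points(gt, roi.vertices * s)
        rois_hist[name] = PolygonROI(hv, closed=True, label=roi.label)
    bh = rois_hist["brain"].vertices
    if (
        bh[:, 0].min() < 0 or bh[:, 1].min() < 0
        or bh[:, 0].max() > hist_shape[1] or bh[:, 1].max() > hist_shape[0]
    ):
        raise ValueError(
            "ground-truth warp pushes the brain outside the histology frame; "
            "reduce warp_amplitude_px or lateral_stretch"
        )

    # --- landmark sites (before rendering, so the fast path below cannot
    # perturb the rng stream they would otherwise share) ------------------
    sites_mov = _landmark_sites(geo) * s
    sites_fix = _warp_points(gt, sites_mov)

    # --- histology raster (render through the approximate inverse) -------
    if render_histology:
        t_inv = _fit_render_inverse(gt, scaled_shape, rng)
        hxs = np.arange(hist_shape[1]) + 0.5
        hys = np.arange(hist_shape[0]) + 0.5
        hgx, hgy = np.meshgrid(hxs, hys)
        hpts = np.column_stack([hgx.ravel(), hgy.ravel()])
        mri_pts = apply_transform(t_inv, hpts) / s
        _, od = _region_fields(mri_pts, geo, params.lesion_contrast)
        chans = []
        for absf in _CHANNEL_ABS:
            i = _HIST_WHITE * np.power(10.0, -absf * od)
            i = i + rng.normal(0.0, params.noise_sd, size=i.shape)
            chans.append(
                np.clip(np.round(i), 0, 255).astype(np.uint8).reshape(hist_shape)
            )
        histology = Image2D(np.stack(chans, axis=-1))
    else:
        histology = Image2D(
            np.full(hist_shape + (3,), int(_HIST_WHITE), dtype=np.uint8)
        )

    # --- landmarks and reference lines -----------------------------------
    idx = np.unique(
        np.round(np.linspace(0, len(sites_mov) - 1, 20)).astype(int)
    )
    landmarks = LandmarkSet.from_arrays(sites_mov[idx], sites_fix[idx])

    (p0, p1) = geo["line"]
    lines = ScaleSpec(
        source_line=LineROI(p0, p1, label="mri-vertical"),
        target_line=LineROI(
            (p0[0] * s, p0[1] * s), (p1[0] * s, p1[1] * s),
            label="hist-vertical",
        ),
    )
    return PhantomPair(
        mri=mri,
        histology=histology,
        gt_forward=gt,
        gt_rois_mri=rois_mri,
        gt_rois_hist=rois_hist,
        landmarks=landmarks,
        lines=lines,
        landmark_sites=(sites_mov, sites_fix),
        params=params,
    )


def landmark_subsample(
    pair: PhantomPair, k: int, jitter_px: float = 0.0,
    seed: Optional[int] = None,
) -> LandmarkSet:
    """Draw ``k`` landmarks from the phantom's ground-truth sites, with
    optional Gaussian positional jitter emulating operator imprecision."""
    mov, fix = pair.landmark_sites
    n = len(mov)
    if k < 3:
        raise ValueError("need at least 3 landmarks")
    if k > n:
        raise ValueError(f"only {n} ground-truth sites available")
    rng = np.random.default_rng(pair.params.seed if seed is None else seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    mov_k = mov[idx].copy()
    fix_k = fix[idx].copy()
    if jitter_px > 0:
        mov_k += rng.normal(0.0, jitter_px, mov_k.shape)
        fix_k += rng.normal(0.0, jitter_px, fix_k.shape)
    return LandmarkSet.from_arrays(mov_k, fix_k)


def measure_percent_changes(pair: PhantomPair) -> Tuple[float, float]:
    """Lesion-vs-contralateral percent change measured on each modality:
    mean MR intensity on the MRI side, stain optical density on the
    histology side (both via the ground-truth measurement circles).
    Returns ``(pc_mri, pc_hist_od)``."""
    from .metrics import lfb_od, percent_change, roi_mean

    les = roi_mean(pair.mri, pair.gt_rois_mri["lesion"]).mean_intensity
    con = roi_mean(pair.mri, pair.gt_rois_mri["contralateral"]).mean_intensity
    pc_mri = percent_change(les, con)
    bg = pair.background_roi_hist
    od_les = lfb_od(pair.histology, pair.gt_rois_hist["lesion"], bg).od
    od_con = lfb_od(pair.histology, pair.gt_rois_hist["contralateral"], bg).od
    pc_hist = percent_change(od_les, od_con)
    return pc_mri, pc_hist
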