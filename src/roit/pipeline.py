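"""The ROI-transfer pipeline.

Both transfer directions share one idea: the deformable registration always
runs at histology resolution (registering at the higher resolution preserves
detail), and ROIs cross the resolution gap as vectors, never as resampled
rasters.

MRI -> histology:
  1. compute the scale factor from the two vertical reference lines;
  2. vector-scale the ROIs and raster-scale the MR slice up to histology
     resolution;
  3. rasterize the scaled ROIs and pack them with the scaled slice into a
     three-channel composite (one channel is the image, so at most two ROIs
     travel per run);
  4. thin-plate-spline register the composite onto the histology frame
     (masks resampled nearest-neighbor to stay binary);
  5. split the registered composite back into channels and trace the mask
     channels into polygons — the ROIs in histology coordinates.

Histology -> MRI is the mirror image: the histology-side composite is
registered onto the *scaled-MRI* frame, the recovered mask outlines are
traced into polygons there, and the polygons are vector-downscaled to
native MRI coordinates (the raster itself is never shrunk).

Throughout, the source MR and histology rasters are treated as read-only:
every product lives in new arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize as sk_resize

from .imagio import Image2D, to_grayscale
from .registration import (
    LandmarkSet,
    TPSTransform,
    fit_tps,
    pullback_grid,
    warp_image,
)
from .roi_core import (
    SMALL_ROI_PX,
    LineROI,
    MaskROI,
    PolygonROI,
    mask_to_polygon,
    rasterize,
    scale_polygon,
)

__all__ = [
    "ScaleSpec",
    "CompositeImage",
    "ROITResult",
    "compute_scale",
    "make_composite",
    "decompose_composite",
    "resize_image",
    "transform_mri_to_histology",
    "transform_histology_to_mri",
]

#: Binarization threshold for warped 8-bit mask channels.  Nearest-neighbor
#: resampling keeps channels at {0, 255}, so this is a safety net only.
MASK_THRESHOLD = 127


@dataclass(frozen=True)
class ScaleSpec:
    """The two straight-line selections marking the vertical slice size on
    the source and target images; their length ratio fixes the scale."""

    source_line: LineROI
    target_line: LineROI


@dataclass(frozen=True)
class CompositeImage:
    """Three equal-shape 8-bit channels: one intensity, up to two masks."""

    channels: np.ndarray  # (H, W, 3) uint8
    roles: Dict[str, int]  # e.g. {"intensity": 0, "roi_1": 1, "roi_2": 2}

    @property
    def shape(self) -> Tuple[int, int]:
        return self.channels.shape[:2]

    def as_image(self) -> Image2D:
        return Image2D(self.channels)


@dataclass(frozen=True)
class ROITResult:
    """Everything a transfer run produces."""

    transformed_rois: List[PolygonROI]
    registered_source: Image2D
    scale_factor: float
    provenance: Dict[str, object]


def compute_scale(spec: ScaleSpec) -> float:
    """Euclidean length ratio target / source of the two reference lines."""
    ls, lt = spec.source_line.length, spec.target_line.length
    if ls <= 0 or lt <= 0:  # LineROI already forbids zero, belt and braces
        raise ValueError("reference lines must have positive length")
    return lt / ls


def resize_image(img: Image2D, s: float) -> Image2D:
    """Raster-resize an image by factor ``s`` (bilinear)."""
    if s <= 0:
        raise ValueError("scale factor must be positive")
    h = max(1, int(round(img.height * s)))
    w = max(1, int(round(img.width * s)))
    out = sk_resize(
        img.pixels.astype(np.float64), (h, w), order=1, mode="edge",
        anti_aliasing=s < 1,
    )
    if img.pixels.dtype in (np.uint8, np.uint16):
        out = np.clip(np.round(out), 0, img.max_value).astype(img.pixels.dtype)
    else:
        out = out.astype(img.pixels.dtype)
    px = None
    if img.pixel_size_mm is not None:
        px = (img.pixel_size_mm[0] / s, img.pixel_size_mm[1] / s)
    return Image2D(out, px)


def make_composite(source: Image2D, masks: Sequence[MaskROI]) -> CompositeImage:
    """Pack the (grayscale) source and 1–2 ROI masks into three 8-bit
    channels.  The intensity channel is min–max rescaled to 0–255; mask
    channels are {0, 255} and decompose back bit-exactly."""
    if source.is_rgb:
        raise ValueError("composite source must be grayscale")
    masks = list(masks)
    if not 1 <= len(masks) <= 2:
        raise ValueError(
            "1 or 2 masks required: one composite channel carries the image, "
            "so only two channels remain for ROIs"
        )
    for m in masks:
        if m.shape != source.shape:
            raise ValueError(
                f"mask shape {m.shape} != source shape {source.shape}"
            )
    px = source.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    inten = (
        np.zeros(source.shape, np.uint8)
        if hi == lo
        else np.round((px - lo) / (hi - lo) * 255).astype(np.uint8)
    )
    chans = [inten] + [m.to_uint8() for m in masks]
    roles = {"intensity": 0, "roi_1": 1}
    if len(masks) == 2:
        roles["roi_2"] = 2
    else:
        chans.append(np.zeros(source.shape, np.uint8))
    return CompositeImage(np.stack(chans, axis=-1), roles)


def decompose_composite(comp: CompositeImage) -> Tuple[Image2D, List[MaskROI]]:
    """Split a (possibly warped) composite back into intensity + masks."""
    inten = Image2D(comp.channels[:, :, comp.roles["intensity"]].copy())
    masks = [
        MaskROI(comp.channels[:, :, comp.roles[key]] > MASK_THRESHOLD)
        for key in ("roi_1", "roi_2")
        if key in comp.roles
    ]
    return inten, masks


def _register_composite(
    comp: CompositeImage,
    landmarks: LandmarkSet,
    lambda_reg: float,
    out_shape: Tuple[int, int],
) -> CompositeImage:
    """Warp a composite onto the fixed frame: intensity bilinear, masks
    nearest-neighbor (so they stay binary)."""
    t_inv = fit_tps(landmarks, direction="fixed_to_moving",
                    lambda_reg=lambda_reg)
    grid = pullback_grid(t_inv, out_shape)
    inten = warp_image(
        Image2D(comp.channels[:, :, comp.roles["intensity"]]),
        t_inv, out_shape, interp="linear", grid=grid,
    )
    chans = [inten.pixels]
    for key in ("roi_1", "roi_2"):
        if key in comp.roles:
            chans.append(
                warp_image(
                    Image2D(comp.channels[:, :, comp.roles[key]]),
                    t_inv, out_shape, interp="nearest", grid=grid,
                ).pixels
            )
    while len(chans) < 3:
        chans.append(np.zeros(out_shape, np.uint8))
    return CompositeImage(np.stack(chans, axis=-1), dict(comp.roles))


def _recover_rois(
    masks: Sequence[MaskROI], labels: Sequence[str]
) -> List[List[PolygonROI]]:
    out = []
    for mask, label in zip(masks, labels):
        if mask.area_px == 0:
            raise ValueError(
                f"ROI {label!r} lost in transformation: its mask channel is "
                "empty after registration (check landmarks and frame sizes)"
            )
        polys = mask_to_polygon(mask)
        polys = [
            replace(p, label=label if len(polys) == 1 else f"{label}-{p.label}")
            for p in polys
        ]
        out.append(polys)
    return out


def _provenance(direction, scale, lambda_reg, landmarks, extra=None):
    from . import __version__

    prov = {
        "direction": direction,
        "scale_factor": scale,
        "lambda_reg": lambda_reg,
        "n_landmarks_active": len(landmarks.active_pairs),
        "n_landmarks_total": len(landmarks),
        "channel_roles": {"intensity": 0, "roi_1": 1, "roi_2": 2},
        "software_version": __version__,
    }
    if extra:
        prov.update(extra)
    return prov


def transform_mri_to_histology(
    mri: Image2D,
    rois: Sequence[PolygonROI],
    spec: ScaleSpec,
    landmarks: LandmarkSet,
    lambda_reg: float = 0.0,
    *,
    target_shape: Tuple[int, int],
) -> ROITResult:
    """Transfer ROIs drawn on the MR slice into histology coordinates.

    ``landmarks`` must pair scaled-MRI (moving) with histology (fixed)
    coordinates — the operator places them while looking at the upscaled MR
    image.  ``target_shape`` is the histology raster shape (H, W).
    """
    rois = list(rois)
    s = compute_scale(spec)
    scaled_rois = [scale_polygon(r, s) for r in rois]
    scaled_mri = resize_image(mri if not mri.is_rgb else to_grayscale(mri), s)
    masks = [rasterize(r, scaled_mri.shape) for r in scaled_rois]
    comp = make_composite(scaled_mri, masks)
    reg = _register_composite(comp, landmarks, lambda_reg, target_shape)
    inten, out_masks = decompose_composite(reg)
    labels = [r.label or f"roi_{i+1}" for i, r in enumerate(rois)]
    per_roi = _recover_rois(out_masks, labels)
    return ROITResult(
        transformed_rois=[p for group in per_roi for p in group],
        registered_source=inten,
        scale_factor=s,
        provenance=_provenance("mri_to_histology", s, lambda_reg, landmarks),
    )


def transform_histology_to_mri(
    hist: Image2D,
    rois: Sequence[PolygonROI],
    spec: ScaleSpec,
    landmarks: LandmarkSet,
    lambda_reg: float = 0.0,
    *,
    target_shape: Tuple[int, int],
) -> ROITResult:
    """Transfer ROIs drawn on the histology image into native MRI
    coordinates.

    ``spec.source_line`` sits on the histology image and ``spec.target_line``
    on the MR slice, so ``compute_scale(spec) < 1``.  ``landmarks`` pair
    histology (moving) with scaled-MRI (fixed) coordinates; registration
    still happens at histology resolution, and only the recovered polygons
    are scaled down — as vectors — to the MRI frame of ``target_shape``.
    """
    rois = list(rois)
    s_down = compute_scale(spec)  # histology -> MRI, typically ~0.1
    upscale = 1.0 / s_down
    hist_gray = to_grayscale(hist) if hist.is_rgb else hist
    masks = [rasterize(r, hist_gray.shape) for r in rois]
    comp = make_composite(hist_gray, masks)
    scaled_mri_shape = (
        int(round(target_shape[0] * upscale)),
        int(round(target_shape[1] * upscale)),
    )
    reg = _register_composite(comp, landmarks, lambda_reg, scaled_mri_shape)
    inten, out_masks = decompose_composite(reg)
    labels = [r.label or f"roi_{i+1}" for i, r in enumerate(rois)]
    per_roi = _recover_rois(out_masks, labels)
    final: List[PolygonROI] = []
    for group in per_roi:
        for poly in group:
            small = scale_polygon(poly, s_down)
            area = small.area()
            if area < SMALL_ROI_PX:
                warnings.warn(
                    f"transferred ROI {small.label!r} covers only "
                    f"{area:.0f} px at MRI resolution; very small ROIs are "
                    "unreliable"
                )
            final.append(small)
    return ROITResult(
        transformed_rois=final,
        registered_source=resize_image(inten, s_down),
        scale_factor=s_down,
        provenance=_provenance("histology_to_mri", s_down, lambda_reg,
                               landmarks),
    )
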