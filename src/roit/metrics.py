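"""Measurement and validation statistics.

Covers the quantities used to validate ROI transfer and to relate the two
modalities: Dice overlap between binary regions, mean intensity inside an
ROI, stain optical density with background correction, lesion-versus-
contralateral percent change, and the Pearson correlation between paired
percent changes.

Optical density follows the transmitted-light Beer–Lambert convention on
the red channel (the channel in which a blue myelin stain absorbs most):

    OD = log10( I_background / I_roi )

where ``I_background`` is the mean red intensity over a blank (unstained)
reference region on the same micrograph.  The ratio form makes OD invariant
to global exposure changes, which is what the background correction is for.
An alternative ``mean_inverted`` mode (background-subtracted inverted
intensity) is provided for comparison with analyses that quantified stain
that way; results record which mode produced them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sstats

from .imagio import Image2D
from .roi_core import MaskROI, PolygonROI, rasterize

__all__ = [
    "ROIStats",
    "dice",
    "roi_mean",
    "lfb_od",
    "percent_change",
    "pearson",
]


@dataclass(frozen=True)
class ROIStats:
    mean_intensity: float
    area_px: int
    od: Optional[float] = None
    od_mode: Optional[str] = None


def dice(a: MaskROI, b: MaskROI) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|) between two binary regions."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = a.area_px, b.area_px
    if na == 0 and nb == 0:
        warnings.warn("both masks empty: Dice defined as 1.0")
        return 1.0
    inter = int(np.logical_and(a.pixels, b.pixels).sum())
    return 2.0 * inter / (na + nb)


def _as_mask(roi: Union[PolygonROI, MaskROI], shape) -> MaskROI:
    if isinstance(roi, MaskROI):
        if roi.shape != shape:
            raise ValueError(f"mask shape {roi.shape} != image shape {shape}")
        return roi
    return rasterize(roi, shape)


def roi_mean(img: Image2D, roi: Union[PolygonROI, MaskROI]) -> ROIStats:
    """Mean intensity over the pixels whose centers fall inside the ROI."""
    if img.is_rgb:
        raise ValueError("roi_mean expects a grayscale image; pick a channel")
    mask = _as_mask(roi, img.shape)
    n = mask.area_px
    if n == 0:
        raise ValueError("ROI does not overlap the image frame")
    mean = float(img.pixels[mask.pixels].mean())
    return ROIStats(mean_intensity=mean, area_px=n)


def lfb_od(
    rgb: Image2D,
    roi: Union[PolygonROI, MaskROI],
    background_roi: Union[PolygonROI, MaskROI],
    mode: str = "beer_lambert",
) -> ROIStats:
    """Stain optical density of ``roi`` from the red channel, corrected by a
    blank ``background_roi`` on the same micrograph.

    ``beer_lambert``: OD = log10(mean_red(background) / mean_red(roi)).
    ``mean_inverted``: (255 - mean_red(roi)) - (255 - mean_red(background)),
    an intensity-difference surrogate on the inverted channel.
    """
    if not rgb.is_rgb:
        raise ValueError("lfb_od expects an RGB micrograph")
    red = Image2D(rgb.pixels[:, :, 0], rgb.pixel_size_mm)
    s_roi = roi_mean(red, roi)
    s_bg = roi_mean(red, background_roi)
    if mode == "beer_lambert":
        if s_roi.mean_intensity <= 0:
            raise ValueError("ROI mean red intensity is 0; OD undefined")
        if s_bg.mean_intensity <= 0:
            raise ValueError("background mean red intensity is 0")
        od = float(np.log10(s_bg.mean_intensity / s_roi.mean_intensity))
        if od < 0:
            warnings.warn(
                "background darker than ROI: OD < 0 (check the background "
                "region is blank)"
            )
    elif mode == "mean_inverted":
        od = float(s_bg.mean_intensity - s_roi.mean_intensity)
    else:
        raise ValueError("mode must be 'beer_lambert' or 'mean_inverted'")
    return ROIStats(
        mean_intensity=s_roi.mean_intensity,
        area_px=s_roi.area_px,
        od=od,
        od_mode=mode,
    )


def percent_change(lesion: float, contralateral: float) -> float:
    """100 * (lesion - contralateral) / contralateral."""
    if contralateral == 0:
        raise ValueError("contralateral value is 0; percent change undefined")
    return 100.0 * (lesion - contralateral) / contralateral


def pearson(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson product-moment correlation; returns (r, r^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r = float(sstats.pearsonr(x, y).statistic)
    return r, r * r
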