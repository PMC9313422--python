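"""Image containers and pre-processing primitives.

The workflow handles two kinds of 2D raster: a low-resolution grayscale MR
slice (e.g. one plane of an MPF map) and a high-resolution RGB histology
micrograph.  Pre-processing before ROI transfer consists of cropping the
slice to the brain, splitting an RGB micrograph into channels, converting to
grayscale, and optionally inverting the chosen channel so that stained
structures appear bright like on the MR image.

Coordinate convention used throughout the package: origin at the top-left
pixel *corner*, x rightward, y downward; pixel ``(row i, col j)`` covers the
half-open square ``[j, j+1) x [i, i+1)`` so its center is ``(j+0.5, i+0.5)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "Image2D",
    "CropRect",
    "read_image",
    "write_image",
    "split_channels",
    "merge_channels",
    "to_grayscale",
    "invert",
    "crop",
]

#: ITU-R 601 luminance weights, the ImageJ default for weighted RGB->gray.
LUMA_WEIGHTS_601 = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class Image2D:
    """A 2D grayscale or RGB raster with bit depth and optional pixel size.

    Parameters
    ----------
    pixels : ndarray
        ``(H, W)`` grayscale or ``(H, W, 3)`` RGB array.  dtype uint8,
        uint16 or floating.
    pixel_size_mm : tuple of float, optional
        Physical pixel size ``(dy, dx)`` in millimetres.
    """

    pixels: np.ndarray
    pixel_size_mm: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2D or 2Dx3, got shape {px.shape}")
        if px.ndim == 3 and px.shape[2] != 3:
            raise ValueError(f"color images must have 3 channels, got {px.shape[2]}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if px.dtype not in (np.uint8, np.uint16) and not np.issubdtype(px.dtype, np.floating):
            raise ValueError(f"unsupported dtype {px.dtype}; use uint8, uint16 or float")
        if self.pixel_size_mm is not None:
            dy, dx = self.pixel_size_mm
            if dy <= 0 or dx <= 0:
                raise ValueError("pixel_size_mm entries must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> Tuple[int, int]:
        """(height, width)."""
        return self.pixels.shape[:2]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def bit_depth(self):
        """8, 16 or the string ``"float"``."""
        if self.pixels.dtype == np.uint8:
            return 8
        if self.pixels.dtype == np.uint16:
            return 16
        return "float"

    @property
    def max_value(self) -> float:
        """Full-scale value: 255 / 65535, or the actual max for float data."""
        if self.pixels.dtype == np.uint8:
            return 255.0
        if self.pixels.dtype == np.uint16:
            return 65535.0
        return float(self.pixels.max())


@dataclass(frozen=True)
class CropRect:
    """Axis-aligned crop rectangle in integer pixels, origin top-left."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("crop width and height must be >= 1")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("crop origin must be non-negative")


def read_image(path: str | os.PathLike) -> Image2D:
    """Read a single-plane TIFF or PNG image.

    RGB images are preserved as three channels; an RGBA alpha channel is an
    error (the workflow never produces one).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        if path.lower().endswith((".tif", ".tiff")):
            px = tifffile.imread(path)
        else:
            px = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"could not read image {path!r}: {exc}") from exc
    px = np.asarray(px)
    if px.ndim == 3 and px.shape[2] > 3:
        raise ValueError(
            f"{path!r} has {px.shape[2]} channels; only grayscale and RGB are supported"
        )
    if px.ndim not in (2, 3):
        raise ValueError(f"{path!r} is not a single-plane 2D image (shape {px.shape})")
    return Image2D(px)


def write_image(img: Image2D, path: str | os.PathLike) -> None:
    """Write to TIFF or PNG (chosen by extension); round trips bit-exactly."""
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, img.pixels)
    else:
        if img.bit_depth == "float":
            raise ValueError("float images must be written as TIFF")
        iio.imwrite(path, img.pixels)


def _require_rgb(img: Image2D) -> None:
    if not img.is_rgb:
        raise ValueError("expected a 3-channel RGB image, got grayscale")


def split_channels(img: Image2D) -> Tuple[Image2D, Image2D, Image2D]:
    """Split an RGB image into (red, green, blue) grayscale images."""
    _require_rgb(img)
    return tuple(
        Image2D(img.pixels[:, :, c].copy(), img.pixel_size_mm) for c in range(3)
    )


def merge_channels(red: Image2D, green: Image2D, blue: Image2D) -> Image2D:
    """Stack three grayscale images back into one RGB image."""
    chans = (red, green, blue)
    if any(c.is_rgb for c in chans):
        raise ValueError("merge_channels expects grayscale inputs")
    if len({c.shape for c in chans}) != 1:
        raise ValueError("channels must share dimensions")
    return Image2D(np.stack([c.pixels for c in chans], axis=-1), red.pixel_size_mm)


def to_grayscale(img: Image2D, weights: Tuple[float, float, float] | None = None) -> Image2D:
    """Convert RGB to grayscale by a weighted channel sum.

    ``weights`` defaults to the ITU-R 601 luminance weights (0.299, 0.587,
    0.114), the ImageJ default; pass ``(1/3, 1/3, 1/3)`` for the unweighted
    mean mode.  Integer inputs are rounded back to their bit depth.
    """
    _require_rgb(img)
    w = LUMA_WEIGHTS_601 if weights is None else weights
    gray = img.pixels.astype(np.float64) @ np.asarray(w, dtype=np.float64)
    if img.pixels.dtype in (np.uint8, np.uint16):
        gray = np.round(gray).astype(img.pixels.dtype)
    return Image2D(gray, img.pixel_size_mm)


def invert(img: Image2D) -> Image2D:
    """Map every pixel value v to ``max_value - v``.

    For 8-/16-bit data ``max_value`` is full scale; for float data it is the
    actual channel maximum, so the inverted image spans the same range.
    Inversion is an involution on integer images.
    """
    if img.is_rgb:
        raise ValueError("invert expects a grayscale image; split channels first")
    return Image2D(
        (img.max_value - img.pixels).astype(img.pixels.dtype), img.pixel_size_mm
    )


def crop(img: Image2D, rect: CropRect) -> Image2D:
    """Crop to ``rect``; the rectangle must lie fully inside the image."""
    if rect.x0 + rect.width > img.width or rect.y0 + rect.height > img.height:
        raise ValueError(
            f"crop rect {rect} exceeds image bounds {img.height}x{img.width}"
        )
    sub = img.pixels[rect.y0 : rect.y0 + rect.height, rect.x0 : rect.x0 + rect.width]
    return Image2D(sub.copy(), img.pixel_size_mm)
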