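"""Landmark-based thin-plate-spline registration.

The deformable step of the ROI-transfer workflow is driven entirely by
paired landmarks that an operator places on anatomically identifiable points
(structure intersections, corner apices, intact slice edges) in the moving
and fixed images.  A thin-plate spline (TPS) interpolates those pairs: an
affine part plus radial-kernel terms

    f(p) = a0 + ax*x + ay*y + sum_i w_i * U(||p - c_i||),   U(r) = r^2 log r^2

fitted per output coordinate, with the classical side conditions
``sum w = 0`` and ``sum w * c = 0`` that remove the kernel's affine
redundancy.  With smoothing ``lambda = 0`` the spline passes exactly through
every landmark; ``lambda > 0`` trades landmark fidelity for smoothness.

Image resampling uses the pull-back convention: the transform handed to
:func:`warp_image` must map *output* (fixed-frame) coordinates to *input*
(moving-frame) coordinates, which is obtained by fitting with the landmark
roles swapped (``direction="fixed_to_moving"``).  Polygon vertices travel
with the forward (``moving_to_fixed``) fit.  Both fits are exact at the
landmarks, so the two routes agree there by construction.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist

from .imagio import Image2D

__all__ = [
    "LandmarkPair",
    "LandmarkSet",
    "TPSTransform",
    "fit_tps",
    "apply_transform",
    "pullback_grid",
    "warp_image",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "MAX_RECOMMENDED_LANDMARKS",
]

#: Soft ceiling on active landmarks; more rarely improves the registration
#: and makes operator placement errors harder to spot.
MAX_RECOMMENDED_LANDMARKS = 30


@dataclass(frozen=True)
class LandmarkPair:
    name: str
    active: bool
    moving: Tuple[float, float]
    fixed: Tuple[float, float]


@dataclass(frozen=True)
class LandmarkSet:
    """Paired moving/fixed 2D landmarks with active flags."""

    pairs: Tuple[LandmarkPair, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def active_pairs(self) -> List[LandmarkPair]:
        return [p for p in self.pairs if p.active]

    def arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        """(moving, fixed) coordinate arrays of the active pairs, (K, 2)."""
        act = self.active_pairs
        mov = np.array([p.moving for p in act], dtype=np.float64).reshape(-1, 2)
        fix = np.array([p.fixed for p in act], dtype=np.float64).reshape(-1, 2)
        return mov, fix

    def swapped(self) -> "LandmarkSet":
        """Exchange moving and fixed roles (for the reverse direction)."""
        return LandmarkSet(
            tuple(
                LandmarkPair(p.name, p.active, p.fixed, p.moving)
                for p in self.pairs
            )
        )

    @staticmethod
    def from_arrays(moving, fixed, names=None, active=None) -> "LandmarkSet":
        moving = np.asarray(moving, float)
        fixed = np.asarray(fixed, float)
        if moving.shape != fixed.shape or moving.ndim != 2:
            raise ValueError("moving and fixed must be matching (K, 2) arrays")
        k = len(moving)
        names = names or [f"Pt-{i}" for i in range(k)]
        active = [True] * k if active is None else list(active)
        return LandmarkSet(
            tuple(
                LandmarkPair(names[i], bool(active[i]),
                             tuple(moving[i]), tuple(fixed[i]))
                for i in range(k)
            )
        )


def _tps_kernel(d2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log(r^2) evaluated from squared distances; U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = d2 * np.log(d2)
    return np.where(d2 > 0.0, out, 0.0)


@dataclass(frozen=True)
class TPSTransform:
    """Fitted thin-plate spline: affine part + kernel weights at controls."""

    affine: np.ndarray        # (2, 3): rows (a0, ax, ay) for x' and y'
    weights: np.ndarray       # (K, 2): kernel coefficients for x' and y'
    control_points: np.ndarray  # (K, 2) source-space anchors
    lambda_reg: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "affine", np.asarray(self.affine, float))
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        object.__setattr__(
            self, "control_points", np.asarray(self.control_points, float)
        )

    @staticmethod
    def identity() -> "TPSTransform":
        aff = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        return TPSTransform(aff, np.zeros((0, 2)), np.zeros((0, 2)))

    def __call__(self, points) -> np.ndarray:
        return apply_transform(self, points)


def fit_tps(
    landmarks: LandmarkSet,
    direction: str = "moving_to_fixed",
    lambda_reg: float = 0.0,
) -> TPSTransform:
    """Fit a TPS mapping one landmark role onto the other.

    Parameters
    ----------
    direction : {"moving_to_fixed", "fixed_to_moving"}
        ``moving_to_fixed`` transports points/vertices drawn on the moving
        image; ``fixed_to_moving`` is the pull-back map used to resample the
        moving image onto the fixed frame.
    lambda_reg : float
        Smoothing added to the kernel matrix diagonal; 0 gives exact
        interpolation of the landmarks.
    """
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be >= 0")
    mov, fix = landmarks.arrays()
    if direction == "fixed_to_moving":
        mov, fix = fix, mov
    elif direction != "moving_to_fixed":
        raise ValueError(f"unknown direction {direction!r}")
    k = len(mov)
    if k < 3:
        raise ValueError(f"need at least 3 active landmark pairs, got {k}")
    if k > MAX_RECOMMENDED_LANDMARKS:
        warnings.warn(
            f"{k} active landmarks; more than {MAX_RECOMMENDED_LANDMARKS} "
            "rarely improves the registration"
        )
    # duplicates in source space make the kernel system singular
    _, counts = np.unique(mov, axis=0, return_counts=True)
    if (counts > 1).any():
        raise ValueError(
            "duplicate source-side landmark coordinates among active pairs; "
            "deactivate or merge the duplicates"
        )
    span = mov - mov.mean(axis=0)
    if np.linalg.matrix_rank(span, tol=1e-9 * max(1.0, np.abs(span).max())) < 2:
        raise ValueError(
            "active landmarks are collinear; add at least one landmark off "
            "the line to define a 2D mapping"
        )

    d2 = ((mov[:, None, :] - mov[None, :, :]) ** 2).sum(-1)
    K = _tps_kernel(d2) + lambda_reg * np.eye(k)
    P = np.column_stack([np.ones(k), mov])
    A = np.zeros((k + 3, k + 3))
    A[:k, :k] = K
    A[:k, k:] = P
    A[k:, :k] = P.T
    b = np.zeros((k + 3, 2))
    b[:k] = fix
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise ValueError(
            "singular TPS system; check landmarks for duplicates or "
            "collinearity"
        ) from exc
    weights = sol[:k]
    affine = sol[k:].T  # (2, 3), columns (const, x, y)
    return TPSTransform(affine, weights, mov, lambda_reg)


def apply_transform(t: TPSTransform, points) -> np.ndarray:
    """Evaluate the spline at (N, 2) points; returns (N, 2)."""
    pts = np.asarray(points, dtype=np.float64)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = t.affine[:, 0] + pts @ t.affine[:, 1:].T
    k = len(t.control_points)
    if k:
        # chunk so the (N, K) distance matrix stays modest for full frames
        chunk = max(1, int(8e6) // max(k, 1))
        for lo in range(0, len(pts), chunk):
            sl = slice(lo, lo + chunk)
            d2 = cdist(pts[sl], t.control_points, "sqeuclidean")
            out[sl] += _tps_kernel(d2) @ t.weights
    return out[0] if single else out


def pullback_grid(t_inverse: TPSTransform, out_shape: Tuple[int, int]) -> np.ndarray:
    """Map every output pixel center through ``t_inverse`` once; returns the
    ``(2, H*W)`` array-index coordinates for resampling.  Useful when
    several channels share one transform."""
    h, w = out_shape
    gx, gy = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    src = apply_transform(t_inverse, np.column_stack([gx.ravel(), gy.ravel()]))
    # continuous coords -> array index coords (pixel center at integer index)
    return np.stack([src[:, 1] - 0.5, src[:, 0] - 0.5])


def _looks_binary(px: np.ndarray) -> bool:
    u = np.unique(px)
    return len(u) <= 2 and set(u.tolist()) <= {0, 1, 255, 65535, 0.0, 1.0}


def warp_image(
    img: Image2D,
    t_inverse: TPSTransform,
    out_shape: Tuple[int, int],
    interp: str = "linear",
    grid: Optional[np.ndarray] = None,
) -> Image2D:
    """Resample ``img`` onto the fixed frame by pulling back through
    ``t_inverse`` (which maps fixed-frame coordinates to moving-frame
    coordinates).  Out-of-bounds samples are filled with 0.  Binary mask
    rasters are always resampled nearest-neighbor to stay binary.

    ``grid`` may carry precomputed :func:`pullback_grid` output so that
    several channels sharing one transform pay for it once.
    """
    if interp not in ("nearest", "linear"):
        raise ValueError("interp must be 'nearest' or 'linear'")
    if interp == "linear" and not img.is_rgb and _looks_binary(img.pixels):
        warnings.warn("binary mask input: switching to nearest-neighbor")
        interp = "nearest"
    order = 0 if interp == "nearest" else 1
    h, w = out_shape
    coords = pullback_grid(t_inverse, out_shape) if grid is None else grid
    if img.is_rgb:
        out = np.stack(
            [
                ndi.map_coordinates(
                    img.pixels[:, :, c].astype(np.float64), coords,
                    order=order, mode="constant", cval=0.0,
                ).reshape(h, w)
                for c in range(3)
            ],
            axis=-1,
        )
    else:
        out = ndi.map_coordinates(
            img.pixels.astype(np.float64), coords,
            order=order, mode="constant", cval=0.0,
        ).reshape(h, w)
    if img.pixels.dtype in (np.uint8, np.uint16):
        out = np.clip(np.round(out), 0, img.max_value).astype(img.pixels.dtype)
    else:
        out = out.astype(img.pixels.dtype)
    return Image2D(out, img.pixel_size_mm)


# ---------------------------------------------------------------------------
# landmark CSV I/O (headerless: name, active, moving_x, moving_y, fixed_x,
# fixed_y — the dialect exported by landmark-placement tools)
# ---------------------------------------------------------------------------

def write_landmarks_csv(ls: LandmarkSet, path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh, quoting=csv.QUOTE_NONNUMERIC)
        for p in ls.pairs:
            wr.writerow(
                [p.name, "true" if p.active else "false",
                 p.moving[0], p.moving[1], p.fixed[0], p.fixed[1]]
            )


def read_landmarks_csv(path) -> LandmarkSet:
    pairs = []
    with open(path, newline="") as fh:
        for ln, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if len(row) != 6:
                raise ValueError(
                    f"{path}: line {ln}: expected 6 columns "
                    f"(name, active, mx, my, fx, fy), got {len(row)}"
                )
            name, active_s = row[0], row[1].strip().lower()
            if active_s not in ("true", "false"):
                raise ValueError(
                    f"{path}: line {ln}: active flag must be true/false, "
                    f"got {row[1]!r}"
                )
            try:
                mx, my, fx, fy = (float(v) for v in row[2:])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {ln}: non-numeric coordinate"
                ) from exc
            pairs.append(
                LandmarkPair(name, active_s == "true", (mx, my), (fx, fy))
            )
    return LandmarkSet(tuple(pairs))
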