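"""Laplacian-of-Gaussian texture enhancement and keypoint screening.

The LoG operator is the Laplacian of an (unnormalized) Gaussian,

    LoG(x, y) = ((x^2 + y^2 - 2 sigma^2) / sigma^4) * exp(-(x^2 + y^2) / 2 sigma^2),

sampled on an odd integer lattice of side ``2*ceil(3*sigma) + 1``.  Its
zero-crossings trace intensity edges; strong crossings (large local response
slope) mark tissue boundaries while weak ones are mostly noise.  Edge-like
responses among candidate keypoints are rejected with the principal-curvature
test (a bound on Hessian trace^2 / determinant), and corner stability is
scored with the Shi-Tomasi minimum structure-tensor eigenvalue.  A fixed
four-level pyramid (640x480 down to 80x60 by 2x area averaging) provides the
multi-scale representation.

The truncated discrete kernel does not sum to zero exactly, so a uniform
additive correction (subtracting the tap mean) is applied; constant images
are then annihilated exactly, which the zero-crossing detector relies on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import downscale_local_mean, resize

from .imaging_io import RasterImage

__all__ = [
    "LoGKernel",
    "LoGResponse",
    "Keypoint",
    "ImagePyramid",
    "gaussian_kernel",
    "log_kernel",
    "apply_log",
    "detect_zero_crossings",
    "edge_response_filter",
    "build_pyramid",
    "shi_tomasi_score",
    "log_enhance",
]

logger = logging.getLogger(__name__)

DEFAULT_SIGMA = 1.6  # staging-preprocessing default; exposed in configs

#: Pyramid level sizes as (height, width), finest to coarsest.
PYRAMID_SHAPES = ((480, 640), (240, 320), (120, 160), (60, 80))


def _kernel_radius(sigma: float) -> int:
    return int(math.ceil(3.0 * sigma))


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Unnormalized Gaussian taps exp(-(x^2+y^2)/2 sigma^2); center tap 1."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    r = _kernel_radius(sigma)
    x, y = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="xy")
    return np.exp(-(x**2 + y**2) / (2.0 * sigma**2))


@dataclass(frozen=True)
class LoGKernel:
    """Zero-sum discrete LoG filter taps at scale ``sigma``."""

    taps: np.ndarray
    sigma: float

    @property
    def side(self) -> int:
        return self.taps.shape[0]


def log_kernel(sigma: float, zero_sum: bool = True) -> LoGKernel:
    """Sample the LoG expression on the lattice and zero-sum correct it.

    With ``zero_sum=False`` the raw analytic taps are returned (useful for
    checking the closed-form values, e.g. -2/sigma^2... the origin value is
    -2*sigma^2/sigma^4 = -2/sigma^2).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    r = _kernel_radius(sigma)
    x, y = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="xy")
    rr = x.astype(np.float64) ** 2 + y.astype(np.float64) ** 2
    taps = (rr - 2.0 * sigma**2) / sigma**4 * np.exp(-rr / (2.0 * sigma**2))
    if zero_sum:
        # truncation leaves a small positive residue; remove it uniformly
        taps = taps - taps.mean()
    return LoGKernel(taps=taps, sigma=float(sigma))


@dataclass(frozen=True)
class LoGResponse:
    """Signed LoG filter response, same shape as the source image."""

    values: np.ndarray
    sigma: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def apply_log(img: RasterImage | np.ndarray, sigma: float = DEFAULT_SIGMA) -> LoGResponse:
    """Correlate the image with the zero-sum LoG kernel (reflect padding)."""
    px = img.pixels if isinstance(img, RasterImage) else np.asarray(img, dtype=np.float64)
    k = log_kernel(sigma)
    if px.shape[0] < k.side or px.shape[1] < k.side:
        raise ValueError(
            f"image {px.shape} smaller than LoG kernel {k.side}x{k.side} at sigma={sigma}"
        )
    values = ndimage.correlate(px, k.taps, mode="reflect")
    return LoGResponse(values=values, sigma=float(sigma))


def detect_zero_crossings(resp: LoGResponse, strength_threshold: float = 0.0) -> np.ndarray:
    """Flag pixels where the response changes sign against a 4-neighbor.

    A pixel is kept iff some 4-neighbor has strictly opposite sign and the
    magnitude of the jump ``|resp(p) - resp(q)|`` exceeds the threshold.
    Threshold 0 keeps every sign change ("weak" crossings included).
    """
    if strength_threshold < 0:
        raise ValueError("strength_threshold must be >= 0")
    v = resp.values
    mask = np.zeros(v.shape, dtype=bool)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        q = np.roll(v, shift, axis=axis)
        # roll wraps around; invalidate the wrapped border row/col
        valid = np.ones(v.shape, dtype=bool)
        if axis == 0:
            valid[0 if shift == 1 else -1, :] = False
        else:
            valid[:, 0 if shift == 1 else -1] = False
        opposite = (v * q) < 0
        strong = np.abs(v - q) > strength_threshold
        mask |= valid & opposite & strong
    return mask


@dataclass
class Keypoint:
    """A candidate feature point on a pyramid level."""

    row: int
    col: int
    level: int = 0
    score: float = 0.0  # Shi-Tomasi min-eigenvalue
    edge_ratio: float = float("nan")  # Hessian trace^2 / determinant


def _hessian_at(v: np.ndarray, r: int, c: int) -> tuple[float, float, float]:
    """Central-difference Hessian entries (dxx, dyy, dxy) at an interior pixel."""
    dxx = v[r, c + 1] - 2.0 * v[r, c] + v[r, c - 1]
    dyy = v[r + 1, c] - 2.0 * v[r, c] + v[r - 1, c]
    dxy = (v[r + 1, c + 1] - v[r + 1, c - 1] - v[r - 1, c + 1] + v[r - 1, c - 1]) / 4.0
    return dxx, dyy, dxy


def edge_response_filter(
    resp: LoGResponse, candidates: list[Keypoint], r: float = 10.0
) -> list[Keypoint]:
    """Discard edge-like keypoints via the principal-curvature ratio test.

    A point survives iff the Hessian of the response there has positive
    determinant and ``Tr(H)^2 / Det(H) < (r+1)^2 / r``.  Equal principal
    curvatures give ratio 4 (always kept for r > 1); a high eigenvalue
    ratio -- an edge -- pushes the quantity above the bound.
    """
    if r <= 1:
        raise ValueError(f"curvature ratio bound r must be > 1, got {r}")
    v = resp.values
    bound = (r + 1.0) ** 2 / r
    kept: list[Keypoint] = []
    for kp in candidates:
        if not (1 <= kp.row < v.shape[0] - 1 and 1 <= kp.col < v.shape[1] - 1):
            logger.warning("keypoint (%d, %d) outside interior; skipped", kp.row, kp.col)
            continue
        dxx, dyy, dxy = _hessian_at(v, kp.row, kp.col)
        det = dxx * dyy - dxy * dxy
        tr = dxx + dyy
        if det <= 0:
            continue  # saddle or degenerate: reject
        ratio = tr * tr / det
        if ratio < bound:
            kp.edge_ratio = ratio
            kept.append(kp)
    return kept


@dataclass(frozen=True)
class ImagePyramid:
    """The fixed four-level multi-scale pyramid, 640x480 down to 80x60."""

    levels: tuple[RasterImage, ...]

    def __post_init__(self) -> None:
        shapes = tuple(im.shape for im in self.levels)
        if shapes != PYRAMID_SHAPES:
            raise ValueError(f"pyramid level shapes {shapes} != {PYRAMID_SHAPES}")


def build_pyramid(img: RasterImage) -> ImagePyramid:
    """Resize to 640x480 then halve three times by 2x2 block averaging."""
    base = img.pixels
    if base.shape != PYRAMID_SHAPES[0]:
        base = resize(
            base, PYRAMID_SHAPES[0], order=1, mode="reflect", anti_aliasing=False,
            preserve_range=True,
        )
    levels = [RasterImage(base, source_id=f"{img.source_id}@L0")]
    cur = base
    for lvl in range(1, 4):
        cur = downscale_local_mean(cur, (2, 2))
        levels.append(RasterImage(cur, source_id=f"{img.source_id}@L{lvl}"))
    return ImagePyramid(levels=tuple(levels))


def shi_tomasi_score(
    img: RasterImage | np.ndarray, row: int, col: int, window: int = 5
) -> float:
    """Minimum eigenvalue of the structure tensor over a centered window.

    Gradients are central differences; the tensor is the unweighted sum of
    their outer products.  Zero on constant patches, ~zero on pure linear
    ramps (rank-1 tensor), strictly positive at two-directional structure.
    """
    px = img.pixels if isinstance(img, RasterImage) else np.asarray(img, dtype=np.float64)
    if window % 2 != 1 or window < 3:
        raise ValueError(f"window must be an odd int >= 3, got {window}")
    h = window // 2
    # gradient stencil needs one extra pixel beyond the window
    if not (h + 1 <= row < px.shape[0] - h - 1 and h + 1 <= col < px.shape[1] - h - 1):
        raise ValueError(
            f"window {window} at ({row},{col}) does not fit inside image {px.shape}"
        )
    patch = px[row - h - 1 : row + h + 2, col - h - 1 : col + h + 2]
    gy, gx = np.gradient(patch)
    gy, gx = gy[1:-1, 1:-1], gx[1:-1, 1:-1]
    a = float(np.sum(gx * gx))
    b = float(np.sum(gx * gy))
    c = float(np.sum(gy * gy))
    # closed-form min eigenvalue of [[a, b], [b, c]]
    return 0.5 * ((a + c) - math.sqrt((a - c) ** 2 + 4.0 * b * b))


def log_enhance(img: RasterImage, sigma: float = DEFAULT_SIGMA,
                mode: str = "sharpen") -> RasterImage:
    """Texture-enhance an image with the LoG operator.

    ``mode='sharpen'`` (Laplacian sharpening, the preprocessing default)
    subtracts the LoG response from the image: intensity structure is kept
    and boundaries are steepened, since the response is negative just
    inside an edge and positive just outside.  ``mode='response'`` returns
    the raw signed response itself (edges only, intensity discarded).
    """
    resp = apply_log(img, sigma)
    if mode == "sharpen":
        values = img.pixels - resp.values
    elif mode == "response":
        values = resp.values
    else:
        raise ValueError(f"mode must be 'sharpen' or 'response', got {mode!r}")
    return RasterImage(values, spacing=img.spacing, source_id=img.source_id)
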