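"""Data augmentation: resize, crop, flip, rotate.

Two pipelines are used downstream.  Training draws a randomized view per
image (random resized crop, flips, rotation) so gradient steps see varied
geometry; clustering uses only resize + central crop so the features being
clustered are clean and deterministic.

Every random draw is a pure function of ``(spec.seed, draw_index)``: the
same pair always yields the same augmented image, which makes training
runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize, rotate

from .imaging_io import RasterImage

__all__ = ["AugmentSpec", "augment_image", "central_crop", "resize_image"]


@dataclass(frozen=True)
class AugmentSpec:
    """Parameters of the stochastic augmentation stream.

    ``rotation_degrees`` is a tuple of candidate angles in [0, 360); one is
    drawn uniformly per view.  ``crop_scale`` bounds the area fraction of
    the random crop before it is resized back to ``out_size``.
    """

    out_size: tuple[int, int] = (64, 64)
    allow_flip_h: bool = True
    allow_flip_v: bool = False
    rotation_degrees: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    crop: str = "random"  # {"random", "central"}
    crop_scale: tuple[float, float] = (0.95, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.out_size[0] <= 0 or self.out_size[1] <= 0:
            raise ValueError(f"out_size must be positive, got {self.out_size}")
        if any(not (0 <= d < 360) for d in self.rotation_degrees):
            raise ValueError("rotation angles must lie in [0, 360)")
        if self.crop not in ("random", "central"):
            raise ValueError(f"crop must be 'random' or 'central', got {self.crop!r}")


def resize_image(img: RasterImage, size: tuple[int, int]) -> RasterImage:
    """Bilinear resize to (h, w), preserving the intensity range."""
    if img.shape == tuple(size):
        return img
    px = resize(img.pixels, size, order=1, mode="reflect", anti_aliasing=False,
                preserve_range=True)
    return RasterImage(px, source_id=img.source_id)


def central_crop(img: RasterImage, size: tuple[int, int]) -> RasterImage:
    """Centered half-open crop; odd margins floor toward the origin."""
    h, w = size
    if h > img.height or w > img.width:
        raise ValueError(f"crop {size} larger than image {img.shape}")
    r0 = (img.height - h) // 2
    c0 = (img.width - w) // 2
    return RasterImage(img.pixels[r0 : r0 + h, c0 : c0 + w], spacing=img.spacing,
                       source_id=img.source_id)


def _rng_for(spec: AugmentSpec, draw_index: int) -> np.random.Generator:
    # independent, reproducible stream per (seed, draw)
    return np.random.default_rng(np.random.SeedSequence((spec.seed, draw_index)))


def augment_image(img: RasterImage, spec: AugmentSpec, draw_index: int) -> RasterImage:
    """Draw one augmented view of ``img``.

    Order: (random or central) crop -> resize to ``out_size`` -> flips ->
    rotation.  Non-right-angle rotations use bilinear interpolation with
    reflect fill; right angles are exact pixel permutations.
    """
    rng = _rng_for(spec, draw_index)
    h, w = img.shape
    oh, ow = spec.out_size

    if spec.crop == "central":
        ch, cw = min(oh, h), min(ow, w)
        view = central_crop(img, (ch, cw))
    else:
        scale = rng.uniform(*spec.crop_scale)
        ch = max(1, min(h, int(round(h * np.sqrt(scale)))))
        cw = max(1, min(w, int(round(w * np.sqrt(scale)))))
        r0 = int(rng.integers(0, h - ch + 1))
        c0 = int(rng.integers(0, w - cw + 1))
        view = RasterImage(img.pixels[r0 : r0 + ch, c0 : c0 + cw],
                           source_id=img.source_id)

    view = resize_image(view, (oh, ow))
    px = view.pixels

    if spec.allow_flip_h and rng.random() < 0.5:
        px = px[:, ::-1]
    if spec.allow_flip_v and rng.random() < 0.5:
        px = px[::-1, :]

    if spec.rotation_degrees:
        angle = float(rng.choice(spec.rotation_degrees))
        if angle % 90 == 0:
            px = np.rot90(px, k=int(angle // 90))
        elif angle != 0.0:
            px = rotate(px, angle, order=1, mode="reflect", preserve_range=True)

    if px.shape != (oh, ow):  # 90/270 rot of a non-square output swaps dims
        px = resize(px, (oh, ow), order=1, mode="reflect", anti_aliasing=False,
                    preserve_range=True)
    return RasterImage(np.ascontiguousarray(px), source_id=img.source_id)
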