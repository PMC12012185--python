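"""Training-time geometric preprocessing and dataset normalization statistics.

These are the transformations a detector-training pipeline applies before it
ever sees a micrograph: aspect-preserving resize to a fixed width (800 px by
default), random horizontal/vertical flips, and per-channel normalization by
the mean and standard deviation of the *training* split only.  Every
geometric op maps image and bounding boxes with the same transform, so
ground truth stays glued to the pixels.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .core import Box

__all__ = ["resize_to_width", "flip", "normalization_stats"]


def _round_half_away(x: float) -> int:
    """Round half away from zero (platform-independent, unlike banker's)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def resize_to_width(
    image: np.ndarray,
    boxes: Sequence[Box] = (),
    target_width: int = 800,
) -> tuple[np.ndarray, list[Box], float]:
    """Resize an image to a fixed width, preserving aspect ratio.

    The height becomes ``round(h * target_width / w)`` (half away from
    zero); boxes are scaled by the single factor ``target_width / w`` on
    both axes and stay float.

    Returns
    -------
    (resized_image, scaled_boxes, scale)
    """
    if target_width <= 0:
        raise ValueError(f"target_width must be positive, got {target_width}")
    h, w = image.shape[:2]
    scale = target_width / w
    new_h = _round_half_away(h * scale)
    if w == target_width:
        out = image
    else:
        out = _sk_resize(
            image, (new_h, target_width), order=1, preserve_range=True,
            anti_aliasing=scale < 1.0,
        ).astype(image.dtype)
    scaled = [
        Box(b.x_min * scale, b.y_min * scale, b.x_max * scale, b.y_max * scale,
            b.confidence)
        for b in boxes
    ]
    return out, scaled, scale


def flip(
    image: np.ndarray,
    boxes: Sequence[Box] = (),
    axis: str = "horizontal",
) -> tuple[np.ndarray, list[Box]]:
    """Mirror an image and its boxes about the vertical or horizontal midline.

    ``axis="horizontal"`` mirrors left-right (x -> width - x);
    ``axis="vertical"`` mirrors top-bottom.  Applying the same flip twice
    restores the original exactly.
    """
    h, w = image.shape[:2]
    if axis == "horizontal":
        out = image[:, ::-1].copy()
        flipped = [
            Box(w - b.x_max, b.y_min, w - b.x_min, b.y_max, b.confidence)
            for b in boxes
        ]
    elif axis == "vertical":
        out = image[::-1, :].copy()
        flipped = [
            Box(b.x_min, h - b.y_max, b.x_max, h - b.y_min, b.confidence)
            for b in boxes
        ]
    else:
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    return out, flipped


def normalization_stats(images: Iterable[np.ndarray]) -> tuple[float, float]:
    """Pooled pixelwise mean and standard deviation of an image set.

    Computed streaming (single pass over sums and squared sums) so a full
    2448x1920 training set never needs to be in memory at once.  This must
    be called on the *training* split only — validation or test pixels
    leaking into the statistics is a form of data leakage.

    Raises
    ------
    ValueError
        If no image is given, or every pixel is identical (std would be 0
        and normalization undefined).
    """
    n = 0
    s = 0.0
    ss = 0.0
    for img in images:
        a = np.asarray(img, dtype=np.float64)
        n += a.size
        s += float(a.sum())
        ss += float(np.square(a).sum())
    if n == 0:
        raise ValueError("normalization_stats needs at least one image")
    mean = s / n
    var = max(ss / n - mean * mean, 0.0)
    if var == 0.0:
        raise ValueError(
            "all pixels identical: standard deviation is zero, "
            "normalization undefined"
        )
    return mean, math.sqrt(var)
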