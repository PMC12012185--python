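"""Classical multi-scale blob detector for stomata, and the detector backend contract.

The production-grade detector for this problem is a trained two-stage
network; training and running it needs GPUs, trained weights and the real
image corpus, none of which belong in a desk-scale toolkit.  What this
module provides instead is

* a deterministic classical baseline — an anisotropic multi-scale
  Difference-of-Gaussian (DoG) band-pass on the contrast-normalized image,
  with local-maximum extraction, scale-derived boxes and per-image
  normalized confidences — strong enough on synthetic imprints to exercise
  every downstream stage (counting rules, density, mAP50 evaluation); and
* the I/O contract any external backend must satisfy: COCO-style detection
  JSON adapted into a validated :class:`~stomakit.core.DetectionSet`, plus
  the training-configuration schema (:class:`TrainingConfig`) an external
  training job consumes.

Because maize stomata are elongated along the cell files, the DoG kernels
are anisotropic: at pyramid scale ``sigma`` the filter uses
``(sigma_y, sigma_x) = (sigma, aspect * sigma)``, and a detection at that
scale becomes a box of height ``box_scale * sigma`` and width
``aspect * box_scale * sigma`` centred on the response peak.  Confidences
are the per-image min-max normalization of the (non-negative) peak
responses onto [0, 1], which is what makes a 50 % confidence cut
meaningful for this backend.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.ndimage import (
    binary_closing,
    gaussian_filter,
    label as cc_label,
    maximum_filter,
)

from .core import Box, DetectionSet, ValidationError, box_iou, clip_box
from .coco_io import read_annotations

__all__ = [
    "DetectorConfig",
    "TrainingConfig",
    "detect",
    "nms",
    "external_detections_adapter",
]

#: Box height per DoG scale sigma, calibrated once against the generator's
#: default stoma geometry (a lobe pair of width W peaks near sigma ~ W / 3.2).
BOX_SCALE = 3.2

#: Sigma ratio of the two Gaussians forming the band-pass.
DOG_RATIO = 1.6


@dataclass(frozen=True)
class DetectorConfig:
    """Configuration of the classical blob detector.

    Parameters
    ----------
    sigma_min, sigma_max : float
        Scale range (pixels) of the DoG pyramid, in units of the *minor*
        (cross-file) stoma axis; covers the expected stoma width range
        divided by :data:`BOX_SCALE`.
    n_scales : int
        Number of geometrically spaced scales.
    response_threshold : float
        Candidate peaks must reach this fraction of the image's maximum
        response, in [0, 1].
    nms_iou : float
        IoU threshold of the greedy non-maximum suppression.
    aspect : float
        Stoma length-to-width ratio; sets kernel anisotropy and box shape.
    """

    sigma_min: float = 4.0
    sigma_max: float = 7.0
    n_scales: int = 6
    response_threshold: float = 0.25
    nms_iou: float = 0.3
    aspect: float = 2.9

    def __post_init__(self) -> None:
        if not (0 < self.sigma_min <= self.sigma_max):
            raise ValidationError("need 0 < sigma_min <= sigma_max")
        if self.n_scales < 1:
            raise ValidationError("n_scales must be >= 1")
        if not (0.0 <= self.response_threshold <= 1.0):
            raise ValidationError("response_threshold must be in [0, 1]")
        if not (0.0 <= self.nms_iou <= 1.0):
            raise ValidationError("nms_iou must be in [0, 1]")
        if self.aspect <= 0:
            raise ValidationError("aspect must be positive")

    def sigmas(self) -> np.ndarray:
        if self.n_scales == 1:
            return np.array([self.sigma_min])
        return np.geomspace(self.sigma_min, self.sigma_max, self.n_scales)

    @classmethod
    def matched(cls, scene_spec, **overrides) -> "DetectorConfig":
        """Config matched to a synthetic scene's stoma geometry."""
        w_mean = scene_spec.stoma_width_mean
        w_sd = scene_spec.stoma_width_sd
        base = dict(
            sigma_min=max((w_mean - 2.5 * w_sd) / BOX_SCALE, 1.0),
            sigma_max=(w_mean + 2.5 * w_sd) / BOX_SCALE,
            aspect=scene_spec.stoma_length_mean / scene_spec.stoma_width_mean,
        )
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"detector": asdict(self)}, fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectorConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc["detector"])


@dataclass(frozen=True)
class TrainingConfig:
    """Schema of a two-stage-detector training configuration.

    This package never trains the network; the schema exists so that
    external training code and this toolkit exchange one validated,
    serializable description of a run (the fields of the usual
    grid search: learning rate, batch size, number of RoI heads, step
    budget) together with the preprocessing contract
    (:mod:`stomakit.preprocess`).
    """

    learning_rate: float = 1e-3
    batch_size: int = 2
    num_roi_heads: int = 256
    max_steps: int = 10_000
    resize_width: int = 800
    flip_horizontal_prob: float = 0.5
    flip_vertical_prob: float = 0.5
    normalization_mean: float | None = None
    normalization_std: float | None = None
    pretrained: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.num_roi_heads < 1:
            raise ValidationError("invalid training hyperparameters")
        if self.max_steps < 1 or self.resize_width < 1:
            raise ValidationError("invalid step/resize settings")
        for p in (self.flip_horizontal_prob, self.flip_vertical_prob):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("flip probabilities must be in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"training": asdict(self)}, fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainingConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc["training"])


def _gauss(arr: np.ndarray, sigma: float | tuple[float, float]) -> np.ndarray:
    """Gaussian smoothing with normalized-convolution boundary handling.

    Zero padding attenuates responses near the frame and reflect padding
    mirrors stoma energy into ghost peaks; renormalizing by the blurred
    indicator of the frame does neither.
    """
    num = gaussian_filter(arr, sigma, mode="constant")
    den = gaussian_filter(np.ones_like(arr), sigma, mode="constant")
    return num / den


def _response_stack(image: np.ndarray, config: DetectorConfig) -> np.ndarray:
    """Anisotropic DoG responses, one slice per scale; stomata respond positive."""
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.0:
        img = img / (255.0 if img.max() <= 255 else 65535.0)
    sd = img.std()
    norm = (img - img.mean()) / (sd if sd > 0 else 1.0)
    # stomata are darker than background: invert so they respond positive
    norm = -norm
    slices = []
    for s in config.sigmas():
        lo = _gauss(norm, (s, config.aspect * s))
        hi = _gauss(norm, (DOG_RATIO * s, config.aspect * DOG_RATIO * s))
        slices.append(lo - hi)
    return np.stack(slices)


def detect(image: np.ndarray, config: DetectorConfig | None = None) -> list[Box]:
    """Detect stomata in one grayscale micrograph.

    Runs the anisotropic multi-scale DoG band-pass, extracts local maxima
    above ``response_threshold`` of the image's peak response, builds a box
    from each maximum's scale, normalizes confidences per image and applies
    greedy NMS.  Deterministic: the same image and config always give the
    same detections.

    An empty or constant image yields an empty list (not an error).
    """
    if config is None:
        config = DetectorConfig()
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValidationError(f"expected a grayscale 2-D image, got shape {img.shape}")
    if img.size == 0 or np.all(img == img.flat[0]):
        return []

    stack = _response_stack(img, config)
    r_max = float(stack.max())
    if r_max <= 0:
        return []
    thr = config.response_threshold * r_max

    local_max = (
        stack == maximum_filter(stack, footprint=np.ones((3, 5, 5)), mode="nearest")
    )
    cand = np.argwhere(local_max & (stack >= thr))

    h, w = img.shape
    sigmas = config.sigmas()
    dark = _darkness_map(img)
    min_bh = BOX_SCALE * float(sigmas[0])
    max_bh = BOX_SCALE * float(sigmas[-1])
    window = (int(round(1.3 * max_bh)), int(round(1.3 * config.aspect * max_bh)))
    # a refined component smaller than a fraction of the smallest admissible
    # stoma is noise; one larger than the largest is a merge of neighbors
    area_bounds = (
        0.2 * config.aspect * min_bh**2,
        1.3 * config.aspect * max_bh**2,
    )
    boxes: list[Box] = []
    for k, y, x in cand:
        s = sigmas[k]
        bh = BOX_SCALE * s
        bw = config.aspect * bh
        conf = float(np.clip(stack[k, y, x] / r_max, 0.0, 1.0))
        box = Box(x - bw / 2, y - bh / 2, x + bw / 2, y + bh / 2, conf)
        box = _refine_box(dark, int(y), int(x), box, window, area_bounds)
        clipped = clip_box(box, w, h)
        if clipped is not None:
            boxes.append(clipped)
    return nms(boxes, config.nms_iou)


def _darkness_map(image: np.ndarray) -> np.ndarray:
    """Lightly smoothed, contrast-normalized darkness (stomata positive)."""
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.0:
        img = img / (255.0 if img.max() <= 255 else 65535.0)
    sd = img.std()
    norm = (img.mean() - img) / (sd if sd > 0 else 1.0)
    return _gauss(norm, 1.5)


def _refine_box(
    dark: np.ndarray,
    cy: int,
    cx: int,
    box: Box,
    window: tuple[int, int],
    area_bounds: tuple[float, float],
) -> Box:
    """Snap a coarse scale-derived box onto the dark figure beneath it.

    Thresholds the local darkness at a fraction of the peak value, closes
    the mask (merging the two guard-cell lobes across the pore slit) and
    takes the bounding box of the connected component under the response
    peak.  Duplicate candidates on one stoma — lobe responses, multiple
    scales — refine to the same component, hence the same box, and
    collapse in the subsequent NMS.  ``window`` is the half-size (y, x) of
    the crop, spanning the largest admissible stoma regardless of the
    candidate's own scale.  Falls back to the coarse box when no usable
    component exists (e.g. heavy blur) or the component is truncated by
    the window.
    """
    h, w = dark.shape
    my, mx = window
    y0, y1 = max(cy - my, 0), min(cy + my + 1, h)
    x0, x1 = max(cx - mx, 0), min(cx + mx + 1, w)
    local = dark[y0:y1, x0:x1]
    ly, lx = cy - y0, cx - x0
    core = local[
        max(ly - 2, 0) : ly + 3, max(lx - 2, 0) : lx + 3
    ]
    peak = float(core.max()) if core.size else 0.0
    if peak <= 0:
        return box
    # raise the cut until the component under the peak separates from its
    # neighbors and fits the admissible stoma size
    for frac in (0.35, 0.5, 0.65):
        mask = local > frac * peak
        mask = binary_closing(mask, structure=np.ones((5, 5)), border_value=0)
        labels, n = cc_label(mask)
        if n == 0:
            continue
        lab = labels[ly, lx]
        if lab == 0:
            # peak pixel just off the mask: take the nearest labelled neighbor
            yy, xx = np.nonzero(labels)
            if yy.size == 0:
                continue
            j = int(np.argmin((yy - ly) ** 2 + (xx - lx) ** 2))
            if (yy[j] - ly) ** 2 + (xx[j] - lx) ** 2 > 9:
                continue
            lab = labels[yy[j], xx[j]]
        ys, xs = np.nonzero(labels == lab)
        lx0, lx1 = xs.min(), xs.max() + 1
        ly0, ly1 = ys.min(), ys.max() + 1
        if (lx1 - lx0) < 1.6 * (ly1 - ly0):
            # a stoma figure is elongated; a near-square component is a
            # single guard-cell lobe cut off from its partner across the
            # pore slit — look for that partner beside it and merge
            merged = _merge_partner_lobe(labels, lab, (lx0, lx1, ly0, ly1), mx)
            if merged is None:
                continue
            lx0, lx1, ly0, ly1 = merged
        bx0, bx1 = x0 + lx0, x0 + lx1
        by0, by1 = y0 + ly0, y0 + ly1
        # a component hugging the window frame is truncated: distrust it
        if (
            (bx0 > x0 or x0 == 0)
            and (by0 > y0 or y0 == 0)
            and (bx1 < x1 or x1 == w)
            and (by1 < y1 or y1 == h)
            and area_bounds[0] <= (bx1 - bx0) * (by1 - by0) <= area_bounds[1]
            and (bx1 - bx0) >= 1.6 * (by1 - by0)
        ):
            return Box(float(bx0), float(by0), float(bx1), float(by1), box.confidence)
    return box


def _merge_partner_lobe(
    labels: np.ndarray,
    lab: int,
    bbox: tuple[int, int, int, int],
    reach: int,
) -> tuple[int, int, int, int] | None:
    """Union a lone guard-cell lobe with its partner across the slit.

    The partner is the nearest other component whose vertical span overlaps
    the lobe's and whose horizontal gap to it is smaller than the lobe's
    own width (the slit is narrower than a lobe).  Returns the merged
    bounds, or ``None`` when no plausible partner exists.
    """
    lx0, lx1, ly0, ly1 = bbox
    lobe_w = lx1 - lx0
    best: tuple[int, tuple[int, int, int, int]] | None = None
    for other in range(1, labels.max() + 1):
        if other == lab:
            continue
        oy, ox = np.nonzero(labels == other)
        if oy.size == 0:
            continue
        ox0, ox1 = ox.min(), ox.max() + 1
        oy0, oy1 = oy.min(), oy.max() + 1
        v_overlap = min(ly1, oy1) - max(ly0, oy0)
        if v_overlap < 0.5 * (ly1 - ly0):
            continue
        gap = max(ox0 - lx1, lx0 - ox1, 0)
        if gap > max(lobe_w, 6) or (ox1 - ox0) > 2.5 * lobe_w:
            continue
        if best is None or gap < best[0]:
            best = (gap, (ox0, ox1, oy0, oy1))
    if best is None:
        return None
    ox0, ox1, oy0, oy1 = best[1]
    return (min(lx0, ox0), max(lx1, ox1), min(ly0, oy0), max(ly1, oy1))


def nms(detections: Sequence[Box], iou_threshold: float) -> list[Box]:
    """Greedy non-maximum suppression.

    Boxes are visited in descending confidence (ties: confidence desc,
    then x_min asc, then y_min asc); a box is kept iff its IoU with every
    already-kept box is below ``iou_threshold``.  The output is a subset
    of the input and the operation is idempotent.
    """
    if not (0.0 <= iou_threshold <= 1.0):
        raise ValidationError(f"iou_threshold {iou_threshold} outside [0, 1]")
    for b in detections:
        if b.confidence is None:
            raise ValidationError("nms requires confidences on every box")
    order = sorted(
        detections, key=lambda b: (-b.confidence, b.x_min, b.y_min)  # type: ignore[operator]
    )
    kept: list[Box] = []
    for b in order:
        if all(box_iou(b, k) < iou_threshold for k in kept):
            kept.append(b)
    return kept


def detect_dataset(
    images: dict[str, np.ndarray], config: DetectorConfig | None = None
) -> DetectionSet:
    """Run :func:`detect` over a mapping image_id -> image."""
    out = DetectionSet()
    for image_id, img in images.items():
        out.add(image_id, detect(img, config))
    return out


def external_detections_adapter(
    path: str | Path, known_image_ids: Sequence[str] | None = None
) -> DetectionSet:
    """Adapt a COCO-style detection file from any backend into a DetectionSet.

    Validates the schema (every entry needs a ``score``) and, when
    ``known_image_ids`` is given, that every referenced image is known —
    unknown ids are reported by name.
    """
    ds = read_annotations(path, kind="detections")
    if known_image_ids is not None:
        known = set(known_image_ids)
        unknown = [i for i in ds.image_ids if i not in known]
        if unknown:
            raise ValidationError(
                f"{path}: detections reference unknown image ids: {sorted(unknown)}"
            )
    assert isinstance(ds, DetectionSet)
    return ds
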