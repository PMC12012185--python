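"""Post-detection filtering and stomata counting rules.

Counting from raw detections uses two cuts, applied in this order and
independently for every image:

1. **Confidence cut** — keep detections with confidence strictly greater
   than 50 % (by default).
2. **Adaptive area cut** — compute the mean bounding-box area of the
   *surviving* detections of that image, then keep only boxes strictly
   larger than half that mean.  Because boxes are border-clipped, a stoma
   less than ~50 % visible at the image edge falls below half of the mean
   full-stoma area and is excluded: the cut acts as a minimum-visibility
   rule.  Mean stomatal size varies by genotype and growth conditions, so
   the mean is never pooled across images — each image sets its own cutoff,
   in a single pass (no fixed-point iteration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import Box, DetectionSet, ValidationError, box_area

__all__ = [
    "CountingConfig",
    "filter_confidence",
    "adaptive_area_filter",
    "count_stomata",
    "count_dataset",
]


@dataclass(frozen=True)
class CountingConfig:
    """Thresholds of the counting pipeline; both cuts are strict (">")."""

    confidence_threshold: float = 0.5
    area_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.confidence_threshold <= 1.0):
            raise ValidationError("confidence_threshold must be in (0, 1]")
        if not (0.0 < self.area_fraction <= 1.0):
            raise ValidationError("area_fraction must be in (0, 1]")


def filter_confidence(detections: Sequence[Box], threshold: float) -> list[Box]:
    """Keep detections with confidence strictly greater than ``threshold``.

    Order is preserved.  The inequality is strict: a confidence exactly at
    the threshold is excluded.
    """
    for b in detections:
        if b.confidence is None:
            raise ValidationError("confidence filter needs confidences on every box")
    return [b for b in detections if b.confidence > threshold]


def adaptive_area_filter(
    detections: Sequence[Box], area_fraction: float = 0.5
) -> list[Box]:
    """Keep detections strictly larger than ``area_fraction`` x the image mean area.

    The mean is taken over this image's detections only (already
    confidence-filtered by the caller), in one pass.  With zero or one
    detection the input is returned unchanged — a single box can never be
    smaller than half its own mean.
    """
    if len(detections) <= 1:
        return list(detections)
    mean_area = sum(box_area(b) for b in detections) / len(detections)
    cutoff = area_fraction * mean_area
    return [b for b in detections if box_area(b) > cutoff]


def count_stomata(
    detections: Sequence[Box], config: CountingConfig | None = None
) -> int:
    """Stomata count of one image: confidence cut, then adaptive area cut."""
    if config is None:
        config = CountingConfig()
    confident = filter_confidence(detections, config.confidence_threshold)
    return len(adaptive_area_filter(confident, config.area_fraction))


def count_dataset(
    detections: DetectionSet, config: CountingConfig | None = None
) -> dict[str, int]:
    """Per-image counts; each image is processed independently."""
    return {
        image_id: count_stomata(boxes, config)
        for image_id, boxes in detections.items()
    }
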