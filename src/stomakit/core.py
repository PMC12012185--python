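"""Domain types for stomatal micrograph annotation and detection.

Coordinate convention
---------------------
All boxes are axis-aligned, in float pixel coordinates with the origin at the
top-left corner of the image, x increasing rightward and y increasing downward.
Boxes are stored as corners ``(x_min, y_min, x_max, y_max)``; the COCO
``[x, y, width, height]`` form is converted at the I/O boundary only.

Detections carry a ``confidence`` in [0, 1]; ground-truth boxes do not.
Boxes extending past the image bounds are clipped to the image at load time,
so every downstream area computation (notably the per-image visibility
filter) operates on the *visible* extent of a stoma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "Box",
    "ImageRecord",
    "GroundTruthSet",
    "DetectionSet",
    "SplitAssignment",
    "ValidationError",
    "box_area",
    "box_iou",
    "clip_box",
    "QUALITY_GROUPS",
    "SPLIT_NAMES",
]

#: The three image-quality strata: minimal artefacts, out-of-focus blur,
#: and imprint/imaging artefacts (air bubbles etc.).
QUALITY_GROUPS = ("default", "blur", "artefact")

#: Canonical split names, in allocation order.
SPLIT_NAMES = ("train", "val", "test")


class ValidationError(ValueError):
    """Raised when annotations, detections or configs violate the data model."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned bounding box in pixel coordinates (corners, origin top-left).

    Parameters
    ----------
    x_min, y_min, x_max, y_max : float
        Corner coordinates; ``x_max > x_min`` and ``y_max > y_min`` are
        required (strictly positive area).
    confidence : float, optional
        Detection confidence in [0, 1]. ``None`` for ground truth.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValidationError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max}) must have positive width and height"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"confidence {self.confidence} outside [0, 1]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def to_xywh(self) -> tuple[float, float, float, float]:
        """COCO-style ``[x, y, width, height]`` form."""
        return (self.x_min, self.y_min, self.width, self.height)

    @classmethod
    def from_xywh(
        cls, x: float, y: float, w: float, h: float, confidence: float | None = None
    ) -> "Box":
        return cls(x, y, x + w, y + h, confidence)


def box_area(box: Box) -> float:
    """Area of a box in squared pixels: ``(x_max − x_min)·(y_max − y_min)``."""
    return box.area


def box_iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; symmetric, in [0, 1]."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def clip_box(box: Box, width: float, height: float) -> Box | None:
    """Clip a box to the image rectangle ``[0, width] × [0, height]``.

    Returns ``None`` when the box lies entirely outside the image (zero
    visible area after clipping).
    """
    x0 = max(box.x_min, 0.0)
    y0 = max(box.y_min, 0.0)
    x1 = min(box.x_max, float(width))
    y1 = min(box.y_max, float(height))
    if x1 <= x0 or y1 <= y0:
        return None
    return Box(x0, y0, x1, y1, box.confidence)


@dataclass(frozen=True)
class ImageRecord:
    """One micrograph: dimensions, quality stratum and plant/genotype identity.

    ``micrometers_per_pixel`` is the physical calibration of the optics;
    it is optional here but *required* for any density computation — the
    package never invents a physical scale.
    """

    image_id: str
    width: int
    height: int
    quality_group: str = "default"
    plant_id: str = ""
    genotype: str = ""
    micrometers_per_pixel: float | None = None
    file: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(
                f"image {self.image_id!r}: non-positive dimensions "
                f"{self.width}x{self.height}"
            )
        if self.quality_group not in QUALITY_GROUPS:
            raise ValidationError(
                f"image {self.image_id!r}: unknown quality_group "
                f"{self.quality_group!r}; expected one of {QUALITY_GROUPS}"
            )


class _BoxSet:
    """Mapping image_id -> list of Box, with set-algebra conveniences."""

    #: whether member boxes must carry a confidence score
    requires_confidence = False

    def __init__(self, boxes: Mapping[str, Iterable[Box]] | None = None) -> None:
        self._boxes: dict[str, list[Box]] = {}
        if boxes:
            for image_id, bs in boxes.items():
                self._boxes[str(image_id)] = list(bs)
        self._validate()

    def _validate(self) -> None:
        for image_id, bs in self._boxes.items():
            for b in bs:
                if self.requires_confidence and b.confidence is None:
                    raise ValidationError(
                        f"image {image_id!r}: detection box without confidence"
                    )

    @property
    def image_ids(self) -> list[str]:
        return list(self._boxes.keys())

    def boxes(self, image_id: str) -> list[Box]:
        return list(self._boxes.get(image_id, []))

    def add(self, image_id: str, boxes: Iterable[Box]) -> None:
        self._boxes.setdefault(image_id, []).extend(boxes)
        self._validate()

    def n_boxes(self) -> int:
        return sum(len(bs) for bs in self._boxes.values())

    def items(self):
        return self._boxes.items()

    def __contains__(self, image_id: str) -> bool:
        return image_id in self._boxes

    def __len__(self) -> int:
        return len(self._boxes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, _BoxSet):
            return NotImplemented
        return self._boxes == other._boxes

    def __repr__(self) -> str:
        return (
            f"{type(self).__name__}({len(self)} images, {self.n_boxes()} boxes)"
        )


class GroundTruthSet(_BoxSet):
    """Per-image ground-truth annotation boxes (no confidences)."""

    requires_confidence = False


class DetectionSet(_BoxSet):
    """Per-image detection boxes; every box carries a confidence."""

    requires_confidence = True


@dataclass(frozen=True)
class SplitAssignment:
    """A train/val/test partition of image ids, plus the seed that made it."""

    assignment: Mapping[str, str]
    seed: int = 0

    def __post_init__(self) -> None:
        bad = {i: s for i, s in self.assignment.items() if s not in SPLIT_NAMES}
        if bad:
            raise ValidationError(f"unknown split labels: {bad}")

    def split(self, name: str) -> list[str]:
        """Image ids assigned to one split, in assignment order."""
        return [i for i, s in self.assignment.items() if s == name]

    def sizes(self) -> dict[str, int]:
        out = dict.fromkeys(SPLIT_NAMES, 0)
        for s in self.assignment.values():
            out[s] += 1
        return out

    def subset(self, sets: _BoxSet, name: str) -> dict[str, list[Box]]:
        """Boxes of ``sets`` restricted to one split."""
        return {i: sets.boxes(i) for i in self.split(name) if i in sets}
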