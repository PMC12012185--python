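"""Readers and writers for COCO-style box annotations and image manifests.

Ground truth and detections are exchanged as COCO-style JSON: an ``images``
array (integer ``id``, ``file_name``, ``width``, ``height``), an
``annotations`` array with ``bbox`` in ``[x, y, width, height]`` form and a
``category_id``, and a single-entry ``categories`` array (the one class,
"stoma").  Detection entries additionally carry a ``score`` in [0, 1].
Internally everything becomes corner-convention :class:`~stomakit.core.Box`
objects keyed by string image ids; the COCO form exists only at this
boundary.

String image ids are encoded in ``file_name`` (the stem is the id), because
strict COCO requires integer ``id`` fields.  Boxes reaching past the image
rectangle are clipped to it at load time, so the per-image visibility filter
downstream sees the visible extent of each stoma.

Manifests are plain CSV with columns ``image_id, file, width, height,
quality_group, plant_id, genotype, micrometers_per_pixel``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import (
    Box,
    DetectionSet,
    GroundTruthSet,
    ImageRecord,
    ValidationError,
    clip_box,
)

__all__ = [
    "read_annotations",
    "write_annotations",
    "read_manifest",
    "write_manifest",
    "STOMA_CATEGORY_ID",
]

STOMA_CATEGORY_ID = 1
_CATEGORIES = [{"id": STOMA_CATEGORY_ID, "name": "stoma"}]

_MANIFEST_COLUMNS = [
    "image_id",
    "file",
    "width",
    "height",
    "quality_group",
    "plant_id",
    "genotype",
    "micrometers_per_pixel",
]


def _stem(file_name: str) -> str:
    return Path(str(file_name)).stem


def read_annotations(
    path: str | Path, kind: str = "ground-truth"
) -> GroundTruthSet | DetectionSet:
    """Read COCO-style JSON into a :class:`GroundTruthSet` or :class:`DetectionSet`.

    Parameters
    ----------
    path : path
        A COCO-style JSON file.  For ``kind="detections"`` either a full
        COCO dict whose annotation entries carry ``score``, or the bare
        COCO results list ``[{"image_id", "bbox", "score", ...}, ...]``.
    kind : {"ground-truth", "detections"}
        Whether boxes must carry confidences.

    Raises
    ------
    ValidationError
        On schema violations; the message lists every offending annotation id
        rather than silently dropping entries.
    FileNotFoundError
        When ``path`` does not exist.
    """
    if kind not in ("ground-truth", "detections"):
        raise ValueError(f"kind must be 'ground-truth' or 'detections', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with open(path) as fh:
        doc = json.load(fh)

    detections = kind == "detections"
    if isinstance(doc, list):
        if not detections:
            raise ValidationError(
                f"{path}: bare result lists are only valid for detections"
            )
        images: dict = {}
        entries = doc
    elif isinstance(doc, dict):
        images = {img["id"]: img for img in doc.get("images", [])}
        entries = doc.get("annotations", [])
    else:
        raise ValidationError(f"{path}: top level must be a JSON object or array")

    # integer COCO image id -> our string id (file_name stem) and dimensions
    id_map: dict[object, str] = {}
    dims: dict[str, tuple[int, int]] = {}
    for iid, img in images.items():
        sid = _stem(img.get("file_name", str(iid)))
        id_map[iid] = sid
        if "width" in img and "height" in img:
            dims[sid] = (int(img["width"]), int(img["height"]))

    boxes: dict[str, list[Box]] = {sid: [] for sid in id_map.values()}
    problems: list[str] = []
    for k, ann in enumerate(entries):
        ann_id = ann.get("id", k)
        try:
            raw_iid = ann["image_id"]
            x, y, w, h = (float(v) for v in ann["bbox"])
        except (KeyError, TypeError, ValueError):
            problems.append(f"annotation {ann_id}: missing/malformed image_id or bbox")
            continue
        sid = id_map.get(raw_iid, None)
        if sid is None:
            if images:
                problems.append(
                    f"annotation {ann_id}: unknown image_id {raw_iid!r}"
                )
                continue
            sid = str(raw_iid)
        if w <= 0 or h <= 0:
            problems.append(
                f"annotation {ann_id}: degenerate bbox [x={x}, y={y}, w={w}, h={h}]"
            )
            continue
        cat = ann.get("category_id", STOMA_CATEGORY_ID)
        if cat != STOMA_CATEGORY_ID:
            problems.append(
                f"annotation {ann_id}: category_id {cat} != {STOMA_CATEGORY_ID} (stoma)"
            )
            continue
        conf: float | None = None
        if detections:
            if "score" not in ann:
                problems.append(f"annotation {ann_id}: detection missing 'score' field")
                continue
            conf = float(ann["score"])
            if not (0.0 <= conf <= 1.0):
                problems.append(
                    f"annotation {ann_id}: score {conf} outside [0, 1]"
                )
                continue
        box = Box(x, y, x + w, y + h, conf)
        if sid in dims:
            clipped = clip_box(box, *dims[sid])
            if clipped is None:
                problems.append(
                    f"annotation {ann_id}: box entirely outside image {sid!r}"
                )
                continue
            box = clipped
        boxes.setdefault(sid, []).append(box)

    if problems:
        raise ValidationError(
            f"{path}: {len(problems)} invalid entr"
            f"{'y' if len(problems) == 1 else 'ies'}:\n  " + "\n  ".join(problems)
        )
    cls = DetectionSet if detections else GroundTruthSet
    return cls(boxes)


def write_annotations(
    sets: GroundTruthSet | DetectionSet,
    path: str | Path,
    records: Sequence[ImageRecord] | None = None,
) -> None:
    """Write a box set as COCO-style JSON.

    ``records``, when given, supply image dimensions and file names for the
    ``images`` section; images absent from ``records`` get dimension-less
    entries so that ``read(write(x)) == x`` holds regardless.
    """
    path = Path(path)
    detections = isinstance(sets, DetectionSet)
    rec_by_id = {r.image_id: r for r in records} if records else {}

    ordered_ids = list(
        dict.fromkeys([r.image_id for r in records or []] + sets.image_ids)
    )
    images = []
    id_of: dict[str, int] = {}
    for n, sid in enumerate(ordered_ids, start=1):
        id_of[sid] = n
        entry: dict = {"id": n, "file_name": f"{sid}.png"}
        rec = rec_by_id.get(sid)
        if rec is not None:
            entry["width"] = rec.width
            entry["height"] = rec.height
            if rec.file:
                entry["file_name"] = rec.file
        images.append(entry)

    annotations = []
    k = 1
    for sid in ordered_ids:
        for box in sets.boxes(sid):
            x, y, w, h = box.to_xywh()
            ann: dict = {
                "id": k,
                "image_id": id_of[sid],
                "category_id": STOMA_CATEGORY_ID,
                "bbox": [x, y, w, h],
                "area": w * h,
                "iscrowd": 0,
            }
            if detections:
                ann["score"] = box.confidence
            annotations.append(ann)
            k += 1

    doc = {"images": images, "annotations": annotations, "categories": _CATEGORIES}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_manifest(path: str | Path) -> list[ImageRecord]:
    """Read an image manifest CSV into :class:`ImageRecord` objects."""
    df = pd.read_csv(path)
    missing = [c for c in _MANIFEST_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {missing}")
    def _text(row, name: str) -> str:
        value = getattr(row, name, "")
        return "" if pd.isna(value) else str(value)

    records = []
    for row in df.itertuples(index=False):
        umpp = getattr(row, "micrometers_per_pixel", None)
        records.append(
            ImageRecord(
                image_id=str(row.image_id),
                width=int(row.width),
                height=int(row.height),
                quality_group=str(row.quality_group),
                plant_id=_text(row, "plant_id"),
                genotype=_text(row, "genotype"),
                micrometers_per_pixel=None if pd.isna(umpp) else float(umpp),
                file=_text(row, "file"),
            )
        )
    return records


def write_manifest(records: Sequence[ImageRecord], path: str | Path) -> None:
    """Write :class:`ImageRecord` objects as a manifest CSV."""
    df = pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "file": r.file,
                "width": r.width,
                "height": r.height,
                "quality_group": r.quality_group,
                "plant_id": r.plant_id,
                "genotype": r.genotype,
                "micrometers_per_pixel": r.micrometers_per_pixel,
            }
            for r in records
        ],
        columns=_MANIFEST_COLUMNS,
    )
    df.to_csv(path, index=False)
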