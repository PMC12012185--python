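"""Stomatal density per plant and genotype-level summaries.

A plant's stomatal density (stomata per square millimetre of leaf area) is
the arithmetic mean of its per-image stomata counts — nine micrographs per
plant in the standard sampling layout — divided by the physical area one
micrograph covers.  The physical scale (micrometres per pixel) is a
microscope calibration and must be supplied; the module never invents one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core import ImageRecord, ValidationError

__all__ = [
    "DensityRecord",
    "density_from_counts",
    "image_area_mm2",
    "densities_from_manifest",
    "summarize_genotype",
]

#: Images per plant in the standard sampling layout.
IMAGES_PER_PLANT = 9


@dataclass(frozen=True)
class DensityRecord:
    """Per-plant counts and the derived density in stomata per mm^2."""

    plant_id: str
    genotype: str
    counts: tuple[int, ...]
    image_area_mm2: float
    density: float


def density_from_counts(counts: Sequence[int], image_area: float) -> float:
    """Stomatal density: mean per-image count divided by the image area (mm^2).

    Warns (but proceeds) when the number of images differs from the
    standard nine — imprint failures (bubbles, blur) do cost images in
    practice.
    """
    if len(counts) == 0:
        raise ValidationError("density needs at least one count")
    if any(c < 0 for c in counts):
        raise ValidationError("counts must be non-negative")
    if image_area <= 0:
        raise ValidationError(f"image_area must be positive, got {image_area}")
    if len(counts) != IMAGES_PER_PLANT:
        warnings.warn(
            f"density computed from {len(counts)} images "
            f"(standard layout is {IMAGES_PER_PLANT})",
            stacklevel=2,
        )
    return (sum(counts) / len(counts)) / image_area


def image_area_mm2(record: ImageRecord) -> float:
    """Physical area of one micrograph in mm^2, from its calibration.

    ``width * height * (um/px)^2 * 1e-6``.  Raises when the record carries
    no ``micrometers_per_pixel``: the scale is a microscope calibration
    that must be measured, not defaulted.
    """
    if record.micrometers_per_pixel is None:
        raise ValidationError(
            f"image {record.image_id!r} has no micrometers_per_pixel; "
            "calibrate the optics (stage micrometer) and set the scale in "
            "the manifest — no default scale is assumed"
        )
    return record.width * record.height * record.micrometers_per_pixel**2 * 1e-6


def densities_from_manifest(
    records: Sequence[ImageRecord], counts: Mapping[str, int]
) -> list[DensityRecord]:
    """Group per-image counts by plant and derive one DensityRecord each."""
    by_plant: dict[str, list[ImageRecord]] = {}
    for r in records:
        by_plant.setdefault(r.plant_id, []).append(r)
    out = []
    for plant_id, recs in by_plant.items():
        plant_counts = tuple(counts[r.image_id] for r in recs if r.image_id in counts)
        if not plant_counts:
            continue
        area = image_area_mm2(recs[0])
        out.append(
            DensityRecord(
                plant_id=plant_id,
                genotype=recs[0].genotype,
                counts=plant_counts,
                image_area_mm2=area,
                density=density_from_counts(plant_counts, area),
            )
        )
    return out


def summarize_genotype(records: Sequence[DensityRecord]) -> pd.DataFrame:
    """Mean, standard error and n of plant-level densities per genotype.

    SE is the sample standard deviation over plants divided by sqrt(n);
    with a single plant it is undefined and reported as NaN.
    """
    if not records:
        raise ValidationError("no density records to summarize")
    df = pd.DataFrame(
        {"genotype": [r.genotype for r in records], "density": [r.density for r in records]}
    )
    rows = []
    for genotype, grp in df.groupby("genotype", sort=True):
        n = len(grp)
        mean = grp["density"].mean()
        se = grp["density"].std(ddof=1) / math.sqrt(n) if n > 1 else float("nan")
        rows.append({"genotype": genotype, "mean_density": mean, "se": se, "n": n})
    return pd.DataFrame(rows)
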