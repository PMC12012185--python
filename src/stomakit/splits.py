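"""Stratified train/val/test splitting of image manifests.

Images are stratified by quality group (minimal-artefact, blur, artefact)
so each split sees the same mix of imaging conditions — the guard against
data leakage and optimistic evaluation when near-duplicate conditions
cluster in one stratum.

Allocation is largest-remainder, at two levels: the *global* split sizes
are the largest-remainder rounding of ``fraction x n`` (so 250 images at
0.6/0.2/0.2 give exactly 150/50/50), and each stratum's records are then
allocated to the splits by largest remainder *constrained to those global
totals* — a greedy assignment of the leftover units to the
(stratum, split) cells with the largest fractional remainders, ties broken
by split order (train, val, test) then stratum order.  Per-stratum
rounding alone cannot guarantee the global totals for every stratum mix;
the constrained form keeps both the global sizes exact and every stratum
within one record of its proportional share.

Within a stratum, records are shuffled by a seeded generator before
allocation, so the split is deterministic per seed and byte-for-byte
reproducible.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ImageRecord, SplitAssignment, ValidationError, SPLIT_NAMES

__all__ = ["stratified_split", "write_split", "read_split"]


def _global_targets(n: int, fractions: Sequence[float]) -> list[int]:
    quotas = [n * f for f in fractions]
    counts = [math.floor(q) for q in quotas]
    rem = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def stratified_split(
    records: Sequence[ImageRecord],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Partition records into train/val/test, stratified by quality group.

    Parameters
    ----------
    records : sequence of ImageRecord
        The manifest to split.
    fractions : (train, val, test)
        Must sum to 1 within 1e-9.
    seed : int
        Seeds the within-stratum shuffle; same seed, same split.

    Returns
    -------
    SplitAssignment
        Every record assigned exactly once; global split sizes equal the
        largest-remainder rounding of ``fraction x len(records)``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions {fractions} do not sum to 1 (within 1e-9)")
    if any(f < 0 for f in fractions):
        raise ValidationError("fractions must be non-negative")
    if not records:
        raise ValidationError("no records to split")
    ids = [r.image_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate image ids in manifest")

    n = len(records)
    global_targets = _global_targets(n, fractions)

    strata: dict[str, list[ImageRecord]] = {}
    for r in records:
        strata.setdefault(r.quality_group, []).append(r)
    stratum_names = sorted(strata)

    n_parts = sum(1 for f in fractions if f > 0)
    for name in stratum_names:
        if len(strata[name]) < n_parts:
            warnings.warn(
                f"stratum {name!r} has {len(strata[name])} record(s), fewer "
                f"than the {n_parts} split parts; allocation is best-effort",
                stacklevel=2,
            )

    # per-(stratum, split) floors and remainders
    floors: dict[str, list[int]] = {}
    remainders: list[tuple[float, int, int]] = []  # (-rem, split_idx, stratum_idx)
    leftover: dict[str, int] = {}
    deficits = list(global_targets)
    for si, name in enumerate(stratum_names):
        ns = len(strata[name])
        quotas = [ns * f for f in fractions]
        fl = [math.floor(q) for q in quotas]
        floors[name] = fl
        leftover[name] = ns - sum(fl)
        for pi in range(len(fractions)):
            deficits[pi] -= fl[pi]
            remainders.append((quotas[pi] - fl[pi], pi, si))

    # assign leftover units to the largest remainders, constrained to the
    # global deficits; ties break by split order then stratum order
    alloc = {name: list(floors[name]) for name in stratum_names}
    remainders.sort(key=lambda t: (-t[0], t[1], t[2]))
    for _, pi, si in remainders:
        name = stratum_names[si]
        if leftover[name] > 0 and deficits[pi] > 0:
            alloc[name][pi] += 1
            leftover[name] -= 1
            deficits[pi] -= 1
    # fallback for pathological mixes: place any stranded unit wherever a
    # global deficit remains (never silent — the warning above fired)
    for name in stratum_names:
        while leftover[name] > 0:
            pi = next(i for i, d in enumerate(deficits) if d > 0)
            alloc[name][pi] += 1
            leftover[name] -= 1
            deficits[pi] -= 1

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    assignment: dict[str, str] = {}
    for name in stratum_names:
        recs = strata[name]
        order = rng.permutation(len(recs))
        shuffled = [recs[i] for i in order]
        start = 0
        for pi, part in enumerate(SPLIT_NAMES):
            for r in shuffled[start : start + alloc[name][pi]]:
                assignment[r.image_id] = part
            start += alloc[name][pi]
    # report in manifest order
    ordered = {r.image_id: assignment[r.image_id] for r in records}
    return SplitAssignment(assignment=ordered, seed=seed)


def write_split(split: SplitAssignment, path: str | Path) -> None:
    """Write a split as two-column CSV (image_id, split)."""
    pd.DataFrame(
        {"image_id": list(split.assignment.keys()),
         "split": list(split.assignment.values())}
    ).to_csv(path, index=False)


def read_split(path: str | Path) -> SplitAssignment:
    df = pd.read_csv(path)
    if not {"image_id", "split"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns image_id, split")
    return SplitAssignment(
        assignment=dict(zip(df["image_id"].astype(str), df["split"]))
    )
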