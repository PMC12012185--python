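"""Synthetic maize leaf-imprint micrograph generator with exact ground truth.

Monocot stomata sit in parallel cell files running along the leaf axis, and
their dumbbell-shaped guard-cell pairs show up in nail-polish imprints as
elongated dark figures on a pale, gently textured background.  This module
renders that geometry directly: each stoma is two filled ellipse lobes
flanking a lighter pore slit, placed on jittered rows, drawn over a
low-frequency background texture with Gaussian sensor noise.

Three quality strata mirror the failure modes of real imprint imaging:

``default``
    minimal artefacts (at most a slight focus jitter),
``blur``
    visible out-of-focus blur (Gaussian PSF),
``artefact``
    imprint/imaging artefacts — at least one air-bubble ring per image.

Every image comes with exact bounding-box ground truth (tight analytic
extents of the rendered lobes, border-clipped), so the generator doubles as
the oracle for detector and counting tests.

Reproducibility: one master seed; the per-image bit generator is
``PCG64(SeedSequence([master_seed, image_index]))``, so any subset of a
dataset can be regenerated independently and identically on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import yaml
from skimage.draw import ellipse as draw_ellipse

from .core import Box, GroundTruthSet, ImageRecord, ValidationError, box_iou, clip_box
from .coco_io import write_annotations, write_manifest

__all__ = [
    "SceneSpec",
    "DegradationSpec",
    "Scene",
    "StomaPlacement",
    "InfeasibleSceneError",
    "sample_scene",
    "render_scene",
    "generate_dataset",
]

#: Reference full-frame width (10x objective camera frame).
FULL_WIDTH = 2448
FULL_HEIGHT = 1920

#: Nominal physical calibration at full frame, micrometers per pixel.
#: Typical for a 10x objective on a 2/3-inch sensor; the synthetic manifest
#: carries it so the density pipeline can run end to end.  Real data must be
#: calibrated, never defaulted.
NOMINAL_UM_PER_PX = 0.345

#: Focus jitter allowed in the "default" (minimal-artefact) stratum, px.
DEFAULT_BLUR_BOUND = 0.8


class InfeasibleSceneError(ValidationError):
    """Requested stoma density cannot be placed under the non-overlap rule."""


@dataclass(frozen=True)
class SceneSpec:
    """Geometry of one synthetic imprint scene.

    Lengths are pixels; stoma length runs along the cell files (x axis).
    ``stomata_per_file`` is the mean count per file; each file's count is
    the stochastic rounding of that mean, so a scene targeting
    ``n_files * stomata_per_file`` stomata lands within half a stoma per
    file of the target.

    ``edge_visibility`` is the minimum visible box-area fraction of every
    stoma, enforced per axis by clamping centers away from the frame edge.
    At the default 1.0 every stoma lies fully in frame, which keeps the
    ground-truth count the exact oracle for counting pipelines (the
    border-visibility cut downstream would otherwise drop heavily clipped
    stomata that the ground truth still counts).  Lower it to synthesize
    border-cut stomata.
    """

    width: int = FULL_WIDTH
    height: int = FULL_HEIGHT
    file_spacing: float = 240.0
    stomata_per_file: float = 7.5
    stoma_length_mean: float = 140.0
    stoma_length_sd: float = 14.0
    stoma_width_mean: float = 48.0
    stoma_width_sd: float = 5.0
    orientation_jitter_deg: float = 8.0
    background_level: float = 0.62
    background_texture_amplitude: float = 0.04
    background_texture_scale: float = 300.0
    stoma_contrast: float = 0.28
    slit_contrast: float = 0.12
    max_pair_iou: float = 0.1
    edge_visibility: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("scene dimensions must be positive")
        if self.file_spacing <= 0:
            raise ValidationError("file_spacing must be positive")
        if self.stomata_per_file < 0:
            raise ValidationError("stomata_per_file must be non-negative")
        if self.stoma_length_mean <= 0 or self.stoma_width_mean <= 0:
            raise ValidationError("stoma dimensions must be positive")
        if not (0.0 < self.edge_visibility <= 1.0):
            raise ValidationError("edge_visibility must be in (0, 1]")

    @classmethod
    def small(cls, **overrides) -> "SceneSpec":
        """Quarter-scale preset (612x480) for fast desk-scale runs."""
        base = dict(
            width=612,
            height=480,
            file_spacing=60.0,
            stomata_per_file=7.5,
            stoma_length_mean=35.0,
            stoma_length_sd=3.5,
            stoma_width_mean=12.0,
            stoma_width_sd=1.2,
            background_texture_scale=75.0,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def scale(self) -> float:
        """Linear scale relative to the full 2448-px frame."""
        return self.width / FULL_WIDTH

    @property
    def micrometers_per_pixel(self) -> float:
        """Nominal calibration implied by the frame scale."""
        return NOMINAL_UM_PER_PX / self.scale

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"scene": self.__dict__}, fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc["scene"])


@dataclass(frozen=True)
class DegradationSpec:
    """Image-quality degradation for one stratum.

    ``blur_sigma`` is the Gaussian PSF width in pixels; the ``default``
    stratum is capped at a small focus jitter.  The ``artefact`` stratum
    renders ``bubble_count >= 1`` air-bubble rings.
    """

    group: str = "default"
    blur_sigma: float = 0.4
    bubble_count_mean: float = 0.0
    bubble_radius_range: tuple[float, float] = (20.0, 80.0)
    noise_sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.group not in ("default", "blur", "artefact"):
            raise ValidationError(f"unknown quality group {self.group!r}")
        if self.group == "default" and self.blur_sigma > DEFAULT_BLUR_BOUND:
            raise ValidationError(
                f"default group blur_sigma {self.blur_sigma} exceeds the "
                f"focus-jitter bound {DEFAULT_BLUR_BOUND}"
            )
        if self.group == "artefact" and self.bubble_count_mean < 1.0:
            raise ValidationError("artefact group requires bubble_count_mean >= 1")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValidationError("noise_sigma and blur_sigma must be >= 0")

    @classmethod
    def for_group(cls, group: str, image_scale: float = 1.0) -> "DegradationSpec":
        """Stratum defaults, with blur/bubble sizes scaled to the frame."""
        if group == "default":
            return cls("default", blur_sigma=0.4 * max(image_scale, 0.25),
                       noise_sigma=0.02)
        if group == "blur":
            return cls("blur", blur_sigma=9.0 * image_scale, noise_sigma=0.02)
        if group == "artefact":
            return cls(
                "artefact",
                blur_sigma=0.4 * max(image_scale, 0.25),
                bubble_count_mean=2.5,
                bubble_radius_range=(60.0 * image_scale, 240.0 * image_scale),
                noise_sigma=0.03,
            )
        raise ValidationError(f"unknown quality group {group!r}")


@dataclass(frozen=True)
class StomaPlacement:
    """One stoma: center, guard-cell pair dimensions and orientation."""

    cx: float
    cy: float
    length: float
    width: float
    angle_deg: float

    def tight_box(self) -> Box:
        """Analytic tight bounding box of the two rendered lobes."""
        th = math.radians(self.angle_deg)
        a = self.length / 4.0  # lobe semi-axis along the stoma axis
        b = self.width / 2.0
        ext_x = math.sqrt((a * math.cos(th)) ** 2 + (b * math.sin(th)) ** 2)
        ext_y = math.sqrt((a * math.sin(th)) ** 2 + (b * math.cos(th)) ** 2)
        off = self.length / 4.0
        hx = off * abs(math.cos(th)) + ext_x
        hy = off * abs(math.sin(th)) + ext_y
        return Box(self.cx - hx, self.cy - hy, self.cx + hx, self.cy + hy)


@dataclass(frozen=True)
class Scene:
    """Sampled stoma placements plus their exact ground truth."""

    spec: SceneSpec
    placements: tuple[StomaPlacement, ...]
    seed: int

    def ground_truth_boxes(self) -> list[Box]:
        """Tight boxes clipped to the image rectangle."""
        out = []
        for p in self.placements:
            clipped = clip_box(p.tight_box(), self.spec.width, self.spec.height)
            if clipped is not None:
                out.append(clipped)
        return out


def _stochastic_round(value: float, rng: np.random.Generator) -> int:
    base = math.floor(value)
    return base + (1 if rng.random() < value - base else 0)


def sample_scene(spec: SceneSpec, seed: int | None = None) -> Scene:
    """Sample row-aligned stoma placements for one scene.

    Stomata are laid on jittered parallel cell files; a bounded rejection
    loop enforces pairwise ground-truth IoU <= ``spec.max_pair_iou``.
    Deterministic for a fixed seed.

    Raises
    ------
    InfeasibleSceneError
        When the requested density cannot be placed within the attempt
        budget (overcrowded spec).
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    n_files = max(int(spec.height / spec.file_spacing), 1)
    y0 = (spec.height - (n_files - 1) * spec.file_spacing) / 2.0

    placements: list[StomaPlacement] = []
    boxes: list[Box] = []
    max_attempts = 60
    for f in range(n_files):
        cy_file = y0 + f * spec.file_spacing + rng.uniform(-0.1, 0.1) * spec.file_spacing
        n_here = _stochastic_round(spec.stomata_per_file, rng)
        if n_here == 0:
            continue
        slot_w = spec.width / n_here
        phase = rng.uniform(0.0, 1.0)
        for s in range(n_here):
            placed = False
            for _ in range(max_attempts):
                length = float(
                    np.clip(
                        rng.normal(spec.stoma_length_mean, spec.stoma_length_sd),
                        0.6 * spec.stoma_length_mean,
                        1.4 * spec.stoma_length_mean,
                    )
                )
                width = float(
                    np.clip(
                        rng.normal(spec.stoma_width_mean, spec.stoma_width_sd),
                        0.6 * spec.stoma_width_mean,
                        1.4 * spec.stoma_width_mean,
                    )
                )
                angle = float(
                    rng.uniform(-spec.orientation_jitter_deg, spec.orientation_jitter_deg)
                )
                # small slot jitter: files keep at least an interstomatal
                # cell between neighbors, so spacing stays fairly regular
                cx = ((s + phase) % n_here + rng.uniform(-0.1, 0.1)) * slot_w
                cy = cy_file + rng.uniform(-0.12, 0.12) * spec.file_spacing
                # per-axis margin enforcing the minimum visible fraction
                probe = StomaPlacement(0.0, 0.0, length, width, angle).tight_box()
                hx, hy = probe.x_max, probe.y_max
                lo_x = max(hx * (2.0 * spec.edge_visibility - 1.0), 0.0)
                lo_y = max(hy * (2.0 * spec.edge_visibility - 1.0), 0.0)
                hi_x = max(spec.width - lo_x, lo_x) - 1e-6
                hi_y = max(spec.height - lo_y, lo_y) - 1e-6
                cx = float(np.clip(cx, lo_x, hi_x))
                cy = float(np.clip(cy, lo_y, hi_y))
                cand = StomaPlacement(cx, cy, length, width, angle)
                cand_box = cand.tight_box()
                if all(box_iou(cand_box, b) <= spec.max_pair_iou for b in boxes):
                    placements.append(cand)
                    boxes.append(cand_box)
                    placed = True
                    break
            if not placed:
                raise InfeasibleSceneError(
                    f"could not place stoma {s} of file {f} after "
                    f"{max_attempts} attempts; spec too dense for the "
                    f"non-overlap constraint (IoU <= {spec.max_pair_iou})"
                )
    return Scene(spec=spec, placements=tuple(placements), seed=seed)


def _draw_stoma(canvas: np.ndarray, p: StomaPlacement, spec: SceneSpec) -> None:
    """Two dark guard-cell lobes flanking a lighter pore slit, drawn in place."""
    th = math.radians(p.angle_deg)
    ux, uy = math.cos(th), math.sin(th)
    a = p.length / 4.0
    b = p.width / 2.0
    h, w = canvas.shape
    for sign in (-1.0, 1.0):
        lx = p.cx + sign * (p.length / 4.0) * ux
        ly = p.cy + sign * (p.length / 4.0) * uy
        # skimage rotation is about the row axis; ellipse semi-axes are
        # (rows, cols) = (b, a) so the long axis lies along +x at angle 0
        rr, cc = draw_ellipse(ly, lx, b, a, shape=(h, w), rotation=-th)
        canvas[rr, cc] -= spec.stoma_contrast
    # pore slit between the lobes, slightly lighter
    rr, cc = draw_ellipse(
        p.cy, p.cx, max(p.width / 8.0, 1.0), p.length / 4.5, shape=(h, w), rotation=-th
    )
    canvas[rr, cc] += spec.slit_contrast


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    from scipy.ndimage import gaussian_filter, zoom

    coarse = max(int(spec.background_texture_scale / 8.0), 2)
    gh = max(spec.height // coarse, 2)
    gw = max(spec.width // coarse, 2)
    field_ = rng.normal(size=(gh, gw))
    field_ = gaussian_filter(field_, sigma=1.5, mode="reflect")
    field_ = zoom(field_, (spec.height / gh, spec.width / gw), order=1)[
        : spec.height, : spec.width
    ]
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd * spec.background_texture_amplitude
    return spec.background_level + field_


def _draw_bubbles(
    canvas: np.ndarray, deg: DegradationSpec, rng: np.random.Generator
) -> int:
    """Air-bubble rings: a dark annulus with a slightly brighter interior."""
    h, w = canvas.shape
    n = max(1, int(rng.poisson(max(deg.bubble_count_mean - 1.0, 0.0))) + 1)
    lo, hi = deg.bubble_radius_range
    for _ in range(n):
        r = float(rng.uniform(lo, hi))
        cy = float(rng.uniform(0, h))
        cx = float(rng.uniform(0, w))
        rr, cc = draw_ellipse(cy, cx, r, r, shape=(h, w))
        canvas[rr, cc] += 0.05
        rim = max(r * 0.12, 2.0)
        rr_o, cc_o = draw_ellipse(cy, cx, r, r, shape=(h, w))
        rr_i, cc_i = draw_ellipse(cy, cx, r - rim, r - rim, shape=(h, w))
        ring = np.zeros((h, w), dtype=bool)
        ring[rr_o, cc_o] = True
        ring[rr_i, cc_i] = False
        canvas[ring] -= 0.22
    return n


def render_scene(
    scene: Scene,
    degradation: DegradationSpec | None = None,
    seed: int | None = None,
    dtype=np.uint8,
) -> np.ndarray:
    """Render a sampled scene to a grayscale image.

    The stoma figure (lobes darker than background by
    ``spec.stoma_contrast``) is drawn over a low-frequency background
    texture; the degradation then applies sensor noise, the stratum's
    Gaussian blur, and — for the artefact stratum — air-bubble rings.

    Returns an 8-bit (default) or 16-bit grayscale array of shape
    ``(height, width)``.
    """
    from scipy.ndimage import gaussian_filter

    spec = scene.spec
    if degradation is None:
        degradation = DegradationSpec.for_group("default", spec.scale)
    if seed is None:
        seed = scene.seed
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 1])))

    canvas = _background(spec, rng)
    for p in scene.placements:
        _draw_stoma(canvas, p, spec)
    if degradation.group == "artefact":
        _draw_bubbles(canvas, degradation, rng)
    if degradation.blur_sigma > 0:
        canvas = gaussian_filter(canvas, degradation.blur_sigma, mode="reflect")
    if degradation.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, degradation.noise_sigma, canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    if dtype == np.uint8:
        return np.round(canvas * 255).astype(np.uint8)
    if dtype == np.uint16:
        return np.round(canvas * 65535).astype(np.uint16)
    raise ValueError("dtype must be uint8 or uint16")


def _largest_remainder(total: int, fractions: Sequence[float]) -> list[int]:
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(
            f"fractions {tuple(fractions)} do not sum to 1 (within 1e-9)"
        )
    quotas = [total * f for f in fractions]
    counts = [math.floor(q) for q in quotas]
    rem = total - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def generate_dataset(
    n_images: int,
    out_dir: str | Path,
    group_fractions: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    plants: bool = True,
    seed: int = 0,
    scene_spec: SceneSpec | None = None,
    genotypes: Sequence[str] = ("WT",),
    density_variation: float = 0.25,
    write_images: bool = True,
) -> tuple[list[ImageRecord], GroundTruthSet]:
    """Generate a dataset of synthetic imprint images with ground truth.

    Parameters
    ----------
    n_images : int
        Number of micrographs.  With ``plants=True`` it must be divisible
        by 9 (nine pictures per plant, the sampling layout used for
        density estimation).
    out_dir : path
        Output directory; receives the images (PNG), ``ground_truth.json``
        (COCO), ``manifest.csv`` and ``scene.yaml``.
    group_fractions : three floats summing to 1
        Shares of the default / blur / artefact quality strata, allocated
        by largest remainder.
    seed : int
        Master seed; image *i* uses ``SeedSequence([seed, i])``.
    density_variation : float
        Per-image relative jitter of the mean stomata-per-file count,
        emulating plant-to-plant and leaf-region density differences.
    write_images : bool
        When False, only annotations and the manifest are written (fast
        path for split/count tests that never look at pixels).

    Returns
    -------
    (records, ground_truth)
        The manifest records and the exact ground truth.
    """
    if n_images <= 0:
        raise ValidationError("n_images must be positive")
    if plants and n_images % 9 != 0:
        raise ValidationError(
            f"n_images={n_images} not divisible into plants of nine images"
        )
    spec = scene_spec if scene_spec is not None else SceneSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    group_counts = _largest_remainder(n_images, group_fractions)
    groups: list[str] = []
    for g, c in zip(("default", "blur", "artefact"), group_counts):
        groups.extend([g] * c)
    # interleave strata across plants deterministically
    master = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 0])))
    master.shuffle(groups)  # type: ignore[arg-type]

    records: list[ImageRecord] = []
    gts = GroundTruthSet()
    for i in range(n_images):
        image_id = f"img_{i:04d}"
        plant_id = f"plant_{i // 9:03d}" if plants else f"plant_{i:03d}"
        genotype = genotypes[(i // 9) % len(genotypes)] if plants else genotypes[0]
        img_rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([seed, 2, i]))
        )
        jitter = 1.0 + img_rng.uniform(-density_variation, density_variation)
        img_spec = replace(
            spec, stomata_per_file=spec.stomata_per_file * jitter, seed=0
        )
        scene_seed = int(img_rng.integers(0, 2**31 - 1))
        scene = sample_scene(img_spec, seed=scene_seed)
        gts.add(image_id, scene.ground_truth_boxes())

        file_name = f"{image_id}.png"
        if write_images:
            deg = DegradationSpec.for_group(groups[i], spec.scale)
            img = render_scene(scene, deg, seed=scene_seed)
            iio.imwrite(out_dir / file_name, img)
        records.append(
            ImageRecord(
                image_id=image_id,
                width=spec.width,
                height=spec.height,
                quality_group=groups[i],
                plant_id=plant_id,
                genotype=genotype,
                micrometers_per_pixel=spec.micrometers_per_pixel,
                file=file_name,
            )
        )

    write_manifest(records, out_dir / "manifest.csv")
    write_annotations(gts, out_dir / "ground_truth.json", records)
    spec.to_yaml(out_dir / "scene.yaml")
    return records, gts
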