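"""Synthetic imprint generator: determinism, ground-truth fidelity, strata."""

import numpy as np
import pytest

import stomakit as sk
from stomakit.core import box_iou
from stomakit.synth import DegradationSpec, InfeasibleSceneError, SceneSpec


class TestSampleScene:
    def test_zero_stomata_gives_empty_ground_truth(self):
        spec = SceneSpec.small(stomata_per_file=0.0)
        scene = sk.sample_scene(spec, seed=1)
        assert scene.placements == ()
        assert scene.ground_truth_boxes() == []

    def test_fixed_seed_is_deterministic(self):
        spec = SceneSpec.small()
        a = sk.sample_scene(spec, seed=9)
        b = sk.sample_scene(spec, seed=9)
        assert a.placements == b.placements
        assert a.ground_truth_boxes() == b.ground_truth_boxes()

    def test_different_seeds_differ(self):
        spec = SceneSpec.small()
        assert (
            sk.sample_scene(spec, seed=1).placements
            != sk.sample_scene(spec, seed=2).placements
        )

    def test_target_count_within_ten_percent(self):
        # full frame, 8 files x 7.5 per file -> 60 stomata targeted
        spec = SceneSpec()  # 2448x1920 defaults
        n_files = int(spec.height / spec.file_spacing)
        target = n_files * spec.stomata_per_file
        assert target == 60
        for seed in range(5):
            n = len(sk.sample_scene(spec, seed=seed).placements)
            assert abs(n - target) <= 0.1 * target

    def test_rows_are_aligned_in_files(self):
        spec = SceneSpec.small()
        scene = sk.sample_scene(spec, seed=4)
        ys = np.array([p.cy for p in scene.placements])
        # every stoma center sits within a quarter spacing of a file line
        n_files = int(spec.height / spec.file_spacing)
        y0 = (spec.height - (n_files - 1) * spec.file_spacing) / 2.0
        lines = y0 + np.arange(n_files) * spec.file_spacing
        dist = np.min(np.abs(ys[:, None] - lines[None, :]), axis=1)
        assert dist.max() <= 0.25 * spec.file_spacing

    def test_pairwise_iou_bounded(self):
        spec = SceneSpec.small()
        boxes = sk.sample_scene(spec, seed=3).ground_truth_boxes()
        for i, a in enumerate(boxes):
            for b in boxes[i + 1:]:
                assert box_iou(a, b) <= spec.max_pair_iou + 1e-9

    def test_centers_inside_image(self):
        spec = SceneSpec.small()
        scene = sk.sample_scene(spec, seed=8)
        for p in scene.placements:
            assert 0 <= p.cx < spec.width and 0 <= p.cy < spec.height

    def test_infeasible_density_raises(self):
        spec = SceneSpec.small(stomata_per_file=300.0)
        with pytest.raises(InfeasibleSceneError):
            sk.sample_scene(spec, seed=0)


class TestRenderScene:
    def test_render_is_deterministic(self):
        spec = SceneSpec.small()
        scene = sk.sample_scene(spec, seed=2)
        assert np.array_equal(sk.render_scene(scene), sk.render_scene(scene))

    def test_stoma_pixels_lie_inside_their_boxes(self):
        # noise-free render: every pixel clearly darker than background must
        # belong to some ground-truth box (after border clipping)
        spec = SceneSpec.small(background_texture_amplitude=0.0)
        scene = sk.sample_scene(spec, seed=6)
        deg = DegradationSpec("default", blur_sigma=0.0, noise_sigma=0.0)
        img = sk.render_scene(scene, deg, dtype=np.uint16).astype(float) / 65535
        dark = img < spec.background_level - 0.5 * spec.stoma_contrast
        inside = np.zeros_like(dark)
        for b in scene.ground_truth_boxes():
            inside[int(b.y_min): int(np.ceil(b.y_max)),
                   int(b.x_min): int(np.ceil(b.x_max))] = True
        assert not np.any(dark & ~inside)

    def test_every_box_contains_contrasting_pixels(self):
        spec = SceneSpec.small(background_texture_amplitude=0.0)
        scene = sk.sample_scene(spec, seed=6)
        deg = DegradationSpec("default", blur_sigma=0.0, noise_sigma=0.0)
        img = sk.render_scene(scene, deg, dtype=np.uint16).astype(float) / 65535
        for b in scene.ground_truth_boxes():
            patch = img[int(b.y_min): int(np.ceil(b.y_max)),
                        int(b.x_min): int(np.ceil(b.x_max))]
            assert patch.min() <= spec.background_level - 0.5 * spec.stoma_contrast

    def test_blur_reduces_variance_and_gradient(self):
        spec = SceneSpec.small()
        scene = sk.sample_scene(spec, seed=5)
        sharp = sk.render_scene(scene, DegradationSpec.for_group("default", spec.scale))
        blurred = sk.render_scene(scene, DegradationSpec.for_group("blur", spec.scale))
        assert blurred.astype(float).var() < sharp.astype(float).var()
        g_sharp = np.hypot(*np.gradient(sharp.astype(float))).mean()
        g_blur = np.hypot(*np.gradient(blurred.astype(float))).mean()
        assert g_sharp > g_blur

    def test_artefact_group_adds_bubbles(self):
        spec = SceneSpec.small()
        scene = sk.sample_scene(spec, seed=5)
        base = sk.render_scene(
            scene, DegradationSpec("default", blur_sigma=0.0, noise_sigma=0.0)
        )
        art = sk.render_scene(
            scene,
            DegradationSpec(
                "artefact", blur_sigma=0.0, noise_sigma=0.0,
                bubble_count_mean=3.0, bubble_radius_range=(15.0, 60.0),
            ),
        )
        changed = np.mean(base != art)
        assert changed > 0.01  # bubbles cover a visible image fraction

    def test_uint16_output_supported(self):
        spec = SceneSpec.small()
        scene = sk.sample_scene(spec, seed=1)
        img = sk.render_scene(scene, dtype=np.uint16)
        assert img.dtype == np.uint16


class TestDegradationSpec:
    def test_default_group_blur_bounded(self):
        with pytest.raises(sk.ValidationError):
            DegradationSpec("default", blur_sigma=5.0)

    def test_artefact_group_requires_bubbles(self):
        with pytest.raises(sk.ValidationError):
            DegradationSpec("artefact", bubble_count_mean=0.0)

    def test_group_presets_valid(self):
        for group in ("default", "blur", "artefact"):
            spec = DegradationSpec.for_group(group, 0.25)
            assert spec.group == group


class TestGenerateDataset:
    def test_one_plant_spans_nine_rows(self, clean_dataset):
        _, records, _ = clean_dataset
        assert len(records) == 9
        assert len({r.plant_id for r in records}) == 1

    def test_manifest_and_annotations_on_disk(self, clean_dataset):
        out, records, gts = clean_dataset
        assert (out / "manifest.csv").exists()
        again = sk.read_annotations(out / "ground_truth.json")
        assert again == gts
        assert sk.read_manifest(out / "manifest.csv") == records

    def test_plants_layout_requires_multiple_of_nine(self, tmp_path):
        with pytest.raises(sk.ValidationError, match="divisible"):
            sk.generate_dataset(10, tmp_path, plants=True, seed=0)

    def test_fractions_must_sum_to_one(self, tmp_path):
        with pytest.raises(sk.ValidationError, match="sum to 1"):
            sk.generate_dataset(
                9, tmp_path, group_fractions=(0.5, 0.2, 0.2), seed=0,
                write_images=False,
            )

    def test_group_fractions_respected(self, tmp_path):
        records, _ = sk.generate_dataset(
            18, tmp_path, group_fractions=(0.5, 0.25, 0.25), seed=3,
            scene_spec=SceneSpec.small(), write_images=False,
        )
        groups = [r.quality_group for r in records]
        assert groups.count("default") == 9
        assert groups.count("blur") == 4 or groups.count("blur") == 5
        assert len(groups) == 18

    def test_regeneration_is_reproducible(self, tmp_path):
        spec = SceneSpec.small()
        r1, g1 = sk.generate_dataset(
            9, tmp_path / "a", seed=17, scene_spec=spec, write_images=False
        )
        r2, g2 = sk.generate_dataset(
            9, tmp_path / "b", seed=17, scene_spec=spec, write_images=False
        )
        assert g1 == g2
        assert [x.quality_group for x in r1] == [x.quality_group for x in r2]

    def test_paper_scale_dataset_exceeds_ten_thousand_boxes(self, tmp_path):
        # 252 full-frame images at the default density: >10k annotated stomata
        _, gts = sk.generate_dataset(
            252, tmp_path, plants=True, seed=5, write_images=False
        )
        assert gts.n_boxes() > 10_000
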