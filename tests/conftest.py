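import pathlib

import pytest

import stomakit as sk


@pytest.fixture(scope="session")
def small_spec() -> sk.SceneSpec:
    return sk.SceneSpec.small()


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory, small_spec):
    """Nine clean quarter-scale images with exact ground truth (one plant)."""
    out = tmp_path_factory.mktemp("clean9")
    records, gts = sk.generate_dataset(
        9,
        out,
        group_fractions=(1.0, 0.0, 0.0),
        plants=True,
        seed=101,
        scene_spec=sk.SceneSpec.small(),
    )
    return out, records, gts


@pytest.fixture(scope="session")
def clean_detections(clean_dataset, small_spec):
    """Baseline-detector output on the nine clean images."""
    import imageio.v3 as iio

    out, records, _ = clean_dataset
    config = sk.DetectorConfig.matched(small_spec)
    images = {r.image_id: iio.imread(out / r.file) for r in records}
    return sk.detect_dataset(images, config)
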