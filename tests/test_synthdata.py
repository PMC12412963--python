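"""Scene generator: determinism, label/rendering consistency, presets,
dataset layout."""

import numpy as np
import pytest

from yolocf.synthdata import (CLASS_NAMES, CLASS_PROPORTIONS, SceneSpec,
                              difficulty_presets, generate_scene, read_labels,
                              write_dataset)


def test_fixed_seed_bitwise_repeatable():
    spec = SceneSpec(image_size=128, seed=42)
    img1, lab1 = generate_scene(spec)
    img2, lab2 = generate_scene(spec)
    assert np.array_equal(img1, img2)
    assert np.array_equal(lab1, lab2)


def test_zero_objects_valid_background():
    spec = SceneSpec(image_size=96, objects_per_image=(0, 0), seed=1)
    img, lab = generate_scene(spec)
    assert img.shape == (96, 96, 3) and img.dtype == np.uint8
    assert lab.shape == (0, 5)


def test_requested_object_count_on_large_canvas():
    spec = SceneSpec(image_size=320, objects_per_image=(12, 12),
                     cluster_probability=0.0, occluder_density=0.0, seed=3)
    _, lab = generate_scene(spec)
    assert len(lab) == 12


def test_labels_normalized_and_well_formed():
    for seed in range(5):
        spec = SceneSpec(image_size=128, seed=seed)
        _, lab = generate_scene(spec)
        if len(lab):
            assert (lab[:, 1:] >= 0).all() and (lab[:, 1:] <= 1).all()
            assert (lab[:, 3:] > 0).all()
            assert set(lab[:, 0]) <= set(range(7))


def test_spec_validation():
    with pytest.raises(ValueError):
        SceneSpec(n_classes=9)
    with pytest.raises(ValueError):
        SceneSpec(illumination="noon")
    with pytest.raises(ValueError):
        SceneSpec(background="wall")


def test_mask_box_consistency():
    """Boxes re-measured from instance masks overlap emitted labels with
    IoU >= 0.8 (rendering/label agreement)."""
    from yolocf.postprocess import box_iou_xyxy

    spec = SceneSpec(image_size=160, occluder_density=0.0, seed=5,
                     objects_per_image=(3, 6))
    scene = generate_scene(spec, full=True)
    size = spec.image_size
    assert len(scene.masks) == len(scene.labels)
    checked = 0
    for mask, lab in zip(scene.masks, scene.labels):
        ys, xs = np.nonzero(mask)
        cx, cy, w, h = lab[1:]
        emitted = np.array([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2])
        # frame-clipped fruits keep their amodal label; the rendered mask
        # cannot measure the out-of-frame part, so compare interior fruits
        if len(xs) < 20 or emitted.min() <= 0.01 or emitted.max() >= 0.99:
            continue
        measured = np.array([xs.min(), ys.min(), xs.max() + 1, ys.max() + 1]) / size
        assert box_iou_xyxy(measured, emitted)[0, 0] >= 0.8
        checked += 1
    assert checked >= 2


def test_visible_fraction_floor():
    """Even under heavy occlusion every fruit keeps >= 25% visible."""
    for seed in (6, 16, 26):
        spec = SceneSpec(image_size=160, occluder_density=3.0, seed=seed,
                         objects_per_image=(4, 8))
        scene = generate_scene(spec, full=True)
        assert scene.visible_fractions, "expected at least one fruit"
        assert min(scene.visible_fractions) >= spec.visible_floor


def test_presets_ordering_and_easy_definition():
    presets = difficulty_presets()
    easy, hard = presets["easy"], presets["hard"]
    assert easy.occluder_density == 0.0
    assert np.mean(easy.objects_per_image) <= 5
    assert np.mean(hard.objects_per_image) > np.mean(easy.objects_per_image)


def test_cfruit_like_exhibits_all_condition_types():
    """Across 100 scenes the mixed preset shows all ten difficulty
    conditions at least once."""
    spec = difficulty_presets()["cfruit_like"]
    spec.image_size = 96
    seen = set()
    ss = np.random.SeedSequence(202)
    for child in ss.spawn(100):
        scene = generate_scene(spec, np.random.default_rng(child), full=True)
        seen |= scene.conditions
    from yolocf.synthdata import CONDITION_TYPES
    assert set(CONDITION_TYPES) <= seen


def test_class_balance_proportional():
    spec = difficulty_presets()["cfruit_like"]
    spec.image_size = 64
    counts = np.zeros(7)
    ss = np.random.SeedSequence(7)
    n = 700
    for child in ss.spawn(n):
        scene = generate_scene(spec, np.random.default_rng(child), full=True)
        if len(scene.labels):
            counts[int(scene.labels[0, 0])] += 1
    frac = counts / counts.sum()
    assert np.all(np.abs(frac - CLASS_PROPORTIONS) <= 0.2 * CLASS_PROPORTIONS
                  + 0.02)


# -- dataset writing --------------------------------------------------------

def test_write_dataset_layout_and_roundtrip(tmp_path):
    spec = SceneSpec(image_size=96, seed=9)
    cfg_path = write_dataset(tmp_path / "ds", spec, n_train=8, n_val=2)
    import yaml
    cfg = yaml.safe_load(open(cfg_path))
    assert cfg["nc"] == 7 and cfg["names"] == list(CLASS_NAMES)
    train_imgs = sorted((tmp_path / "ds/images/train").glob("*.png"))
    val_imgs = sorted((tmp_path / "ds/images/val").glob("*.png"))
    assert len(train_imgs) == 8 and len(val_imgs) == 2
    # labels parse and match the generator's output format
    for p in (tmp_path / "ds/labels/train").glob("*.txt"):
        lab = read_labels(p)
        if len(lab):
            assert lab.shape[1] == 5
            assert (lab[:, 1:] >= 0).all() and (lab[:, 1:] <= 1).all()
            assert np.allclose(lab[:, 0], lab[:, 0].astype(int))


def test_write_dataset_refuses_nonempty(tmp_path):
    d = tmp_path / "ds"
    d.mkdir()
    (d / "junk.txt").write_text("x")
    with pytest.raises(FileExistsError):
        write_dataset(d, SceneSpec(image_size=64), 1, 1)
    write_dataset(d, SceneSpec(image_size=64), 1, 1, overwrite=True)


def test_write_dataset_deterministic(tmp_path):
    spec = SceneSpec(image_size=64, seed=4)
    write_dataset(tmp_path / "a", spec, 3, 1)
    write_dataset(tmp_path / "b", spec, 3, 1)
    for rel in ("images/train/00000.png", "labels/train/00002.txt"):
        assert (tmp_path / "a" / rel).read_bytes() \
            == (tmp_path / "b" / rel).read_bytes()
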