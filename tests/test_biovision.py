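import numpy as np
import pytest

from hapi3d.biovision import (CLASS_ORDER, BioVisionModel, GroundTruthPatchSet,
                              SegmentationMetrics, TrainingError, classify,
                              classify_volume, evaluate_f1, extract_features,
                              fit_model)
from hapi3d.volumes import Volume


def test_extract_features_constant_image():
    img = np.empty((6, 6, 3))
    img[..., 0], img[..., 1], img[..., 2] = 60.0, 120.0, 180.0
    feats = extract_features(img)
    assert feats.shape == (6, 6, 4)
    assert np.allclose(feats[..., 0], 60.0)
    assert np.allclose(feats[..., 1], 120.0)
    assert np.allclose(feats[..., 2], 180.0)
    assert np.allclose(feats[..., 3], 120.0)  # luminance = (60+120+180)/3


def test_local_intensity_five_pixel_cross():
    img = np.full((3, 3, 3), 50.0)
    img[1, 1] = 100.0  # center luminance 100, neighbors 50
    feats = extract_features(img, include_center=True)
    assert feats[1, 1, 3] == pytest.approx((100.0 + 4 * 50.0) / 5.0)  # 60
    feats_nc = extract_features(img, include_center=False)
    assert feats_nc[1, 1, 3] == pytest.approx(50.0)


def test_extract_features_rejects_non_rgb():
    with pytest.raises(ValueError):
        extract_features(np.zeros((5, 5)))


def test_patch_set_validation():
    img = np.zeros((4, 4, 3))
    with pytest.raises(ValueError):
        GroundTruthPatchSet([(img, np.full((4, 4), 5))])  # code > 3
    with pytest.raises(ValueError):
        GroundTruthPatchSet([(img, np.zeros((4, 4)))])  # fully unlabeled


def _three_class_patches(rng, n_px=400, jitter=4.0):
    """Well-separated synthetic colors for each class."""
    colors = {1: (110, 75, 45), 2: (205, 160, 175), 3: (246, 246, 246)}
    side = int(np.sqrt(3 * n_px)) + 2
    img = np.empty((side, side, 3))
    lab = np.zeros((side, side), dtype=np.uint8)
    thirds = np.array_split(np.arange(side), 3)
    for code, rows in zip((1, 2, 3), thirds):
        img[rows] = colors[code]
        lab[rows] = code
    img += rng.normal(0, jitter, img.shape)
    return GroundTruthPatchSet([(img, lab)])


def test_fit_model_deterministic(rng):
    patches = _three_class_patches(rng)
    m1 = fit_model(patches, n_components=2, seed=7)
    m2 = fit_model(patches, n_components=2, seed=7)
    for cls in CLASS_ORDER:
        assert np.array_equal(np.asarray(m1.means[cls]), np.asarray(m2.means[cls]))
        assert np.array_equal(np.asarray(m1.weights[cls]), np.asarray(m2.weights[cls]))


def test_fit_model_loglik_traces_monotone(rng):
    patches = _three_class_patches(rng)
    model, logliks = fit_model(patches, n_components=2, seed=0,
                               return_loglik=True)
    for cls, trace in logliks.items():
        diffs = np.diff(np.asarray(trace))
        assert (diffs >= -1e-8).all(), f"non-monotone EM trace for {cls!r}"


def test_fit_model_too_few_pixels():
    img = np.zeros((4, 4, 3))
    lab = np.full((4, 4), 2, dtype=np.uint8)
    lab[0, 0] = 1
    lab[0, 1] = 3
    with pytest.raises(TrainingError):
        fit_model(GroundTruthPatchSet([(img, lab)]), n_components=3)
    with pytest.raises(ValueError):
        fit_model(GroundTruthPatchSet([(img, lab)]), n_components=0)


def test_classify_separable_colors(rng):
    patches = _three_class_patches(rng)
    model = fit_model(patches, n_components=1, seed=0)
    test_img, test_lab = _three_class_patches(np.random.default_rng(5)).patches[0]
    pred = classify(test_img, model)
    assert (pred == test_lab).mean() > 0.99


def test_model_save_load_round_trip(tmp_path, rng):
    patches = _three_class_patches(rng)
    model = fit_model(patches, n_components=2, seed=0)
    back = BioVisionModel.load(model.save(tmp_path / "m.json"))
    img, _ = _three_class_patches(np.random.default_rng(11)).patches[0]
    assert np.array_equal(classify(img, model), classify(img, back))


def test_classify_volume_stacks_planes(rng):
    patches = _three_class_patches(rng)
    model = fit_model(patches, n_components=1, seed=0)
    img, lab = _three_class_patches(np.random.default_rng(2)).patches[0]
    data = np.stack([img, img], axis=2)  # (h, w, 2, 3)
    vol = Volume(data, (25.0, 25.0, 125.0), modality="histology",
                 valid_planes=[True, False])
    seg = classify_volume(vol, model)
    assert seg.modality == "mask"
    assert np.array_equal(seg.data[:, :, 0].astype(bool), lab == 1)
    assert not seg.data[:, :, 1].any()  # invalid plane stays empty
    with pytest.raises(ValueError):
        classify_volume(Volume(np.zeros((4, 4, 2)), (25, 25, 125)), model)


def test_f1_exact_small_case():
    pred = np.array([1, 1, 1, 0])
    truth = np.array([1, 1, 0, 1])
    m = evaluate_f1(pred, truth)
    assert (m.tp, m.fp, m.fn) == (2, 1, 1)
    assert m.precision == pytest.approx(2 / 3)
    assert m.recall == pytest.approx(2 / 3)
    assert m.f1 == pytest.approx(2 / 3)


def test_f1_conventions():
    empty = np.zeros(5)
    m = evaluate_f1(empty, empty)
    assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)
    m = evaluate_f1(empty, np.ones(5))
    assert m.precision == 1.0 and m.recall == 0.0 and m.f1 == 0.0
    with pytest.raises(ValueError):
        evaluate_f1(np.zeros(4), np.zeros(5))


def test_classifier_on_phantom_section(phantom_small, abeta_model):
    # one distorted section vs its ground-truth mask, native geometry
    z = 10
    img = phantom_small.series["abeta"].images[z]
    truth = phantom_small.distorted_masks["abeta"].data[:, :, z]
    pred = classify(np.asarray(img, dtype=float), abeta_model) == 1
    assert evaluate_f1(pred, truth).f1 > 0.8
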