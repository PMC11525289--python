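"""Pixel classification: features, forest training, prediction, threshold."""

import warnings

import numpy as np
import pytest

import twpscope as t
from twpscope import pixelclass as pc
from twpscope import preprocess as pp


def _flat_image(value, shape=(30, 30)):
    return pp.FilterImage(np.full(shape + (3,), value, np.uint8), 1.5)


def test_constant_image_features_are_constant_with_zero_gradient():
    feats, names = pc.extract_features(_flat_image(100))
    for i, name in enumerate(names):
        plane = feats[..., i]
        if name == "grad_mag":
            assert np.allclose(plane, 0.0, atol=1e-4)
        else:
            assert np.allclose(plane, 100.0, atol=1e-3)


def test_darkness_feature_extremes():
    feats, names = pc.extract_features(_flat_image(0))
    assert feats[..., names.index("darkness")].max() == 0
    feats, names = pc.extract_features(_flat_image(255))
    assert feats[..., names.index("darkness")].min() == 255


def test_gaussian_feature_matches_kernel_on_impulse():
    """A unit impulse smoothed at scale sigma reproduces the truncated
    discrete Gaussian kernel, computed independently here."""
    rgb = np.zeros((41, 41, 3), np.uint8)
    rgb[20, 20] = 255
    feats, names = pc.extract_features(pp.FilterImage(rgb, 1.0), scales=(2.0,))
    got = feats[20, :, names.index("R_gauss2")]
    x = np.arange(41) - 20.0
    k1d = np.exp(-(x**2) / (2 * 2.0**2))
    k1d[np.abs(x) > 4 * 2.0] = 0.0  # default truncation at 4 sigma
    k1d /= k1d.sum()
    expected = 255.0 * k1d * k1d[20]
    assert np.allclose(got, expected, atol=1e-3)


def test_empty_scale_list_is_an_error():
    with pytest.raises(ValueError):
        pc.extract_features(_flat_image(10), scales=())


def _toy_labels(n=40):
    """Half the pixels black, half blue: linearly separable classes."""
    rgb = np.zeros((20, n, 3), np.uint8)
    rgb[:, n // 2 :] = (90, 120, 220)
    img = pp.FilterImage(rgb, 1.5)
    rows = np.repeat(np.arange(10), 4)
    cols_fg = np.tile(np.arange(2, 6), 10)
    cols_bg = cols_fg + n // 2
    coords = np.concatenate(
        [np.column_stack([rows, cols_fg]), np.column_stack([rows, cols_bg])]
    )
    classes = np.r_[np.ones(40, int), np.zeros(40, int)]
    return img, pc.LabelSet(coords, classes)


def test_separable_labels_train_to_perfect_oob_accuracy():
    img, labels = _toy_labels()
    feats, names = pc.extract_features(img)
    model = pc.train_classifier(feats, labels, seed=0, feature_names=names)
    assert model.oob_accuracy == 1.0


def test_mislabelled_pixel_lowers_accuracy_without_crashing():
    img, labels = _toy_labels()
    classes = labels.classes.copy()
    classes[0] = 0  # a black pixel labelled background
    flipped = pc.LabelSet(labels.coords, classes)
    feats, names = pc.extract_features(img)
    model = pc.train_classifier(feats, flipped, seed=0, feature_names=names)
    assert model.oob_accuracy < 1.0


def test_single_class_labels_are_an_error():
    img, labels = _toy_labels()
    only_fg = pc.LabelSet(labels.coords[:40], labels.classes[:40])
    feats, _ = pc.extract_features(img)
    with pytest.raises(ValueError, match="both classes"):
        pc.train_classifier(feats, only_fg)


def test_conflicting_labels_are_an_error():
    with pytest.raises(ValueError, match="both classes"):
        pc.LabelSet(np.array([[1, 1], [1, 1]]), np.array([0, 1]))


def test_same_seed_gives_identical_class_maps(small_scene):
    image, truth = small_scene
    enhanced = pp.enhance(image)
    labels = pc.labels_from_truth(enhanced, truth, n_per_class=400, seed=3)
    feats, names = pc.extract_features(enhanced)
    maps = []
    for _ in range(2):
        model = pc.train_classifier(feats, labels, seed=5, feature_names=names)
        maps.append(pc.classify(enhanced, model))
    assert np.array_equal(maps[0].prob, maps[1].prob)


def test_forest_recovers_twp_cores_on_a_scene(small_scene):
    """Core (non-halo) pixels of black particles classify TWP at >= 99%."""
    image, truth = small_scene
    enhanced = pp.enhance(image)
    labels = pc.labels_from_truth(enhanced, truth, seed=0)
    feats, names = pc.extract_features(enhanced)
    model = pc.train_classifier(feats, labels, seed=0, feature_names=names)
    cmap = pc.classify(enhanced, model)
    core = truth.rasters["core"]
    bg = truth.rasters["label"] == 0
    assert cmap.hard[core].mean() >= 0.99  # recall on cores
    assert cmap.hard[bg].mean() <= 0.01  # false-positive rate on background


def test_all_white_image_classifies_as_background():
    cmap = pc.classify(_flat_image(255), pc.RuleModel())
    assert not cmap.hard.any()


def test_exclusion_forces_background_even_over_black_pixels():
    img = _flat_image(0)  # entirely black
    img.exclusion_mask = np.zeros(img.shape, bool)
    img.exclusion_mask[:15] = True
    cmap = pc.classify(img, pc.RuleModel())
    assert not cmap.hard[:15].any()
    assert cmap.hard[15:].all()


def test_binarize_binary_probabilities_equal_hard_map():
    prob = np.zeros((20, 20), np.float32)
    prob[5:10, 5:10] = 1.0
    cmap = pc.ClassMap(prob=prob, hard=prob >= 0.5)
    assert np.array_equal(pc.binarize(cmap), cmap.hard)


def _isodata_oracle(raster: np.ndarray) -> float:
    """IsoData fixed point by direct iteration on the 8-bit histogram."""
    thr = raster.mean()
    for _ in range(200):
        lo = raster[raster <= thr]
        hi = raster[raster > thr]
        new = (lo.mean() + hi.mean()) / 2.0
        if abs(new - thr) < 1e-6:
            break
        thr = new
    return thr


def test_binarize_threshold_sits_between_bimodal_modes():
    rng = np.random.default_rng(0)
    prob = np.where(rng.random((50, 50)) < 0.3, 0.9, 0.1).astype(np.float32)
    prob += rng.normal(0, 0.01, prob.shape).astype(np.float32)
    prob = np.clip(prob, 0, 1)
    cmap = pc.ClassMap(prob=prob, hard=prob >= 0.5)
    mask = pc.binarize(cmap)
    raster = np.round(prob * 255).astype(np.uint8)
    oracle = _isodata_oracle(raster)
    assert 0.1 * 255 < oracle < 0.9 * 255
    # pixels strictly above the fixed point are foreground
    assert np.array_equal(mask, raster > np.floor(oracle))


def test_binarize_degenerate_raster_warns_and_is_empty():
    prob = np.full((10, 10), 0.4, np.float32)
    cmap = pc.ClassMap(prob=prob, hard=prob >= 0.5)
    with pytest.warns(UserWarning, match="degenerate"):
        mask = pc.binarize(cmap)
    assert not mask.any()


def test_organic_distractors_yield_zero_twp_pixels():
    """With organics labelled background, none of their pixels classify TWP."""
    spec = t.SceneSpec(
        width_px=400, height_px=400, n_random=4, halo_width_um=(3, 5),
        size_range_um=(40, 120), organic_per_mm2=6.0, rng_seed=13,
    )
    image, truth = t.generate_scene(spec)
    enhanced = pp.enhance(image)
    labels = pc.labels_from_truth(enhanced, truth, seed=0)
    feats, names = pc.extract_features(enhanced)
    model = pc.train_classifier(feats, labels, seed=0, feature_names=names)
    cmap = pc.classify(enhanced, model)
    organic_ids = [p.id for p in truth.particles if p.cls == "organic"]
    assert organic_ids
    organic_mask = np.isin(truth.rasters["label"], organic_ids)
    assert cmap.hard[organic_mask].sum() == 0


def test_model_roundtrip_through_archive(tmp_path, small_scene):
    image, truth = small_scene
    enhanced = pp.enhance(image)
    labels = pc.labels_from_truth(enhanced, truth, n_per_class=200, seed=1)
    feats, names = pc.extract_features(enhanced)
    model = pc.train_classifier(feats, labels, seed=1, feature_names=names)
    path = model.save(tmp_path / "model.joblib")
    loaded = pc.ForestModel.load(path)
    assert loaded.scales == model.scales
    a = pc.classify(enhanced, model)
    b = pc.classify(enhanced, loaded)
    assert np.array_equal(a.prob, b.prob)
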