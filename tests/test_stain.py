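"""Weighted-HSV positive/negative rule and weak/moderate/strong classifier."""

import numpy as np
import pytest
from skimage.color import rgb2hsv, hsv2rgb

from er_allred import (DetectedCell, PNThresholds, WMSTrainConfig, classify_cells,
                       classify_pn, classify_wms, extract_patch, generate_patchset,
                       train_wms, weighted_hsv, wms_posterior)
from er_allred.stain import WeightedColor, _center_weights


def hsv_block(h, s, v, size=32):
    """Uniform RGB block from HSV on the 0-255 scale."""
    rgb = hsv2rgb(np.array([[[h / 255.0, s / 255.0, v / 255.0]]]))[0, 0]
    return np.tile(np.round(rgb * 255).astype(np.uint8), (size, size, 1))


# ---------------------------------------------------------------- extract_patch

def test_extract_patch_center_and_border():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
    block = extract_patch(img, (32, 32), size=32)
    assert np.array_equal(block, img[16:48, 16:48])
    corner = extract_patch(img, (0, 0), size=32)
    assert corner.shape == (32, 32, 3)  # fully defined via reflection
    assert np.array_equal(corner, extract_patch(img, (0, 0), size=32))
    with pytest.raises(ValueError):
        extract_patch(img, (70, 10))


# ---------------------------------------------------------------- weighted_hsv

def test_weighted_hsv_uniform_block_is_plain_value():
    block = hsv_block(20, 200, 100)
    expected = rgb2hsv(block[:1, :1] / 255.0)[0, 0] * 255.0
    wc = weighted_hsv(block)
    assert wc.wh == pytest.approx(expected[0], abs=1e-9)
    assert wc.wv == pytest.approx(expected[2], abs=1e-9)


def test_weighted_hsv_center_dominates():
    """Brown center quarter in a blue periphery: the weighted hue must sit
    strictly closer to the center hue than the unweighted mean does."""
    block = hsv_block(160, 200, 120)
    block[8:24, 8:24] = hsv_block(20, 200, 120)[8:24, 8:24]
    hsv = rgb2hsv(block / 255.0) * 255.0
    unweighted = hsv[:, :, 0].mean()
    wc = weighted_hsv(block)
    assert wc.wh < unweighted


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_weighted_hsv_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    block = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
    hsv = rgb2hsv(block.astype(np.float64) / 255.0) * 255.0
    c = (32 - 1) / 2.0
    d_max = 32 * np.sqrt(2) / 2.0
    num_h = num_v = den = 0.0
    for i in range(32):
        for j in range(32):
            w = 1.0 - np.hypot(i - c, j - c) / d_max
            assert w > 0
            num_h += w * hsv[i, j, 0]
            num_v += w * hsv[i, j, 2]
            den += w
    wc = weighted_hsv(block)
    assert wc.wh == pytest.approx(num_h / den, abs=1e-9)
    assert wc.wv == pytest.approx(num_v / den, abs=1e-9)


def test_weighted_hsv_mirror_symmetry():
    rng = np.random.default_rng(9)
    block = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
    wc = weighted_hsv(block)
    wm = weighted_hsv(block[:, ::-1])
    assert wc.wh == pytest.approx(wm.wh, abs=1e-9)
    assert wc.wv == pytest.approx(wm.wv, abs=1e-9)
    w = _center_weights(16)
    assert np.allclose(w, w[:, ::-1]) and np.allclose(w, w[::-1, :])


# ---------------------------------------------------------------- PN rule

@pytest.mark.parametrize("wh,wv,expected", [
    (160, 30, "P"),   # dark overrides hue
    (20, 120, "P"),   # brown
    (160, 120, "N"),  # blue, not dark
    (40, 120, "P"),   # boundary: hue exactly at threshold stays positive
    (41, 50, "N"),    # boundary: value exactly at threshold is not dark
])
def test_classify_pn_rule(wh, wv, expected):
    assert classify_pn(WeightedColor(wh, wv)) == expected


def test_pn_thresholds_validation():
    with pytest.raises(ValueError):
        PNThresholds(hue_threshold=300)
    with pytest.raises(ValueError):
        WeightedColor(-1, 0)


# ---------------------------------------------------------------- WMS training

def test_wms_requires_all_classes():
    patches, labels = generate_patchset(5, seed=0, classes=("W", "M"))
    with pytest.raises(ValueError, match="'S'"):
        train_wms(patches, labels, WMSTrainConfig(epochs=1))


def test_wms_held_out_accuracy(trained_wms):
    patches, labels = generate_patchset(60, seed=99, classes=("W", "M", "S"))
    post = wms_posterior(trained_wms, patches)
    pred = [("W", "M", "S")[i] for i in post.argmax(axis=1)]
    acc = np.mean([a == b for a, b in zip(pred, labels)])
    assert acc >= 0.85
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-5)


def test_wms_shuffled_labels_give_chance_accuracy():
    """Training on randomly permuted labels destroys the label-color link:
    accuracy against an independent random labeling sits at chance, and the
    model shows no real skill against the true labels either (it can at
    most memorize each color's plurality permuted label, which is
    uninformative about the true class)."""
    patches, labels = generate_patchset(60, seed=21, classes=("W", "M", "S"))
    rng = np.random.default_rng(0)
    shuffled = rng.permutation(np.array(labels))
    net = train_wms(patches, shuffled, WMSTrainConfig(epochs=8, seed=2))
    test_p, test_l = generate_patchset(100, seed=77, classes=("W", "M", "S"))
    pred = [("W", "M", "S")[i] for i in wms_posterior(net, test_p).argmax(axis=1)]
    random_l = rng.permutation(np.array(test_l))
    acc_random = np.mean([a == b for a, b in zip(pred, random_l)])
    assert acc_random == pytest.approx(1 / 3, abs=0.05)
    acc_true = np.mean([a == b for a, b in zip(pred, test_l)])
    assert acc_true <= 0.5


def test_wms_training_reproducible():
    patches, labels = generate_patchset(10, seed=4, classes=("W", "M", "S"))
    cfg = WMSTrainConfig(epochs=2, seed=8)
    n1 = train_wms(patches, labels, cfg)
    n2 = train_wms(patches, labels, cfg)
    assert n1.meta["loss_history"] == n2.meta["loss_history"]


def test_classify_wms_extremes_and_determinism(trained_wms):
    dark, _ = generate_patchset(1, seed=51, classes=("S",))
    pale, _ = generate_patchset(1, seed=52, classes=("W",))
    assert classify_wms(trained_wms, dark[0]) == "S"
    assert classify_wms(trained_wms, pale[0]) == "W"
    assert classify_wms(trained_wms, dark[0]) == classify_wms(trained_wms, dark[0])


def test_untrained_wms_rejected():
    from er_allred import nn
    from er_allred.stain import default_wms_arch
    net = nn.Network(nn.layers_from_config(default_wms_arch()))
    with pytest.raises(ValueError, match="untrained"):
        classify_wms(net, np.zeros((32, 32, 3), dtype=np.uint8))


# ---------------------------------------------------------------- classify_cells

def test_classify_cells_empty_list(trained_wms):
    img = np.zeros((64, 64, 3), dtype=np.uint8)
    assert classify_cells(img, [], wms_model=trained_wms) == []


def test_all_negative_scene_never_invokes_wms():
    """With no positive cells the intensity classifier must not be touched:
    passing no model at all still succeeds."""
    from conftest import make_scene
    img, truth = make_scene(61, width=192, height=192, n=(8, 0, 0, 0))
    cells = [DetectedCell(n.x, n.y) for n in truth.nuclei]
    out = classify_cells(img, cells, wms_model=None)
    assert [c.label for c in out] == ["N"] * len(cells)
    assert [(c.x, c.y) for c in out] == [(c.x, c.y) for c in cells]  # order kept


def test_classify_cells_matches_ground_truth(trained_wms):
    from conftest import make_scene
    img, truth = make_scene(62, width=320, height=320, n=(10, 10, 10, 10))
    cells = [DetectedCell(n.x, n.y) for n in truth.nuclei]
    out = classify_cells(img, cells, wms_model=trained_wms)
    acc = np.mean([c.label == t for c, t in zip(out, truth.labels)])
    assert acc >= 0.90
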