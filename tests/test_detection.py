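"""Score-map construction, cone fixtures, watershed extraction, detector training."""

import numpy as np
import pytest

from er_allred import (DetectionParams, DetectorTrainConfig, build_score_target,
                       extract_cells, generate_scene, predict_score_map,
                       train_detector)
from er_allred.synthetic import SceneSpec
from conftest import centroid_array, make_scene


# ---------------------------------------------------------------- score target

def test_score_target_linear_cone_values():
    sm = build_score_target(np.array([[50.0, 40.0]]), (100, 100), cell_radius=32)
    assert sm[40, 50] == 1.0                      # at the centroid
    assert sm[40, 50 + 16] == pytest.approx(0.5)  # halfway down the cone
    assert sm[40, 50 + 32] == 0.0                 # clipped at the radius
    assert sm[40 + 40, 50] == 0.0                 # beyond the radius
    assert sm.min() >= 0 and sm.max() <= 1


def test_score_target_empty_and_bounds():
    assert not build_score_target(np.empty((0, 2)), (20, 30)).any()
    with pytest.raises(ValueError):
        build_score_target(np.array([[35.0, 5.0]]), (20, 30))


# ---------------------------------------------------------------- extract_cells

def test_extract_cells_empty_map():
    assert extract_cells(np.zeros((64, 64), dtype=np.float32)) == []


def test_extract_cells_single_cone_recovers_apex():
    sm = build_score_target(np.array([[60.0, 70.0]]), (128, 128), 32)
    cells = extract_cells(sm, DetectionParams())
    assert len(cells) == 1
    assert abs(cells[0].x - 60) <= 1 and abs(cells[0].y - 70) <= 1


def test_extract_cells_splits_merged_cones():
    """Two cones 40 px apart merge at threshold 0.2; the watershed must split
    them into two cells near the apexes. The peak-count oracle is brute
    force: the analytic map has exactly two strict local maxima."""
    cents = np.array([[50.0, 64.0], [90.0, 64.0]])
    sm = build_score_target(cents, (128, 144), 32)
    # oracle: strict 8-neighbour local maxima of the analytic map
    from scipy.ndimage import maximum_filter
    peaks = (sm == maximum_filter(sm, size=3)) & (sm >= 0.999)
    assert peaks.sum() == 2
    # merged at threshold: the midpoint scores above 0.2
    assert sm[64, 70] > 0.2
    cells = extract_cells(sm, DetectionParams())
    assert len(cells) == 2
    for cell, (cx, cy) in zip(cells, cents):
        assert np.hypot(cell.x - cx, cell.y - cy) <= 2


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_oracle_equivalence_non_overlapping_centroids(seed):
    """Targets built from centroids pairwise farther than 2R are recovered
    exactly (+-1 px), matching the generating centroids one to one."""
    rng = np.random.default_rng(seed)
    R = 32
    grid = [(x, y) for y in range(48, 400, 80) for x in range(48, 400, 80)]
    cents = np.array(grid, dtype=float) + rng.uniform(-6, 6, (len(grid), 2))
    d = np.hypot(*(cents[:, None, :] - cents[None, :, :]).T)
    assert (d[np.triu_indices(len(cents), 1)] > 2 * R).all()
    sm = build_score_target(cents, (448, 448), R)
    cells = extract_cells(sm, DetectionParams())
    assert len(cells) == len(cents)
    got = centroid_array(cells)
    for c in np.round(cents):
        assert np.min(np.hypot(*(got - c).T)) <= 1.0


def test_threshold_monotonicity_and_determinism():
    rng = np.random.default_rng(4)
    cents = rng.uniform(40, 216, (12, 2))
    sm = build_score_target(cents, (256, 256), 32)
    counts = []
    for thr in (0.1, 0.2, 0.3, 0.5, 0.7, 0.9):
        cells = extract_cells(sm, DetectionParams(score_threshold=thr,
                                                  min_region_area=10))
        counts.append(len(cells))
    assert counts == sorted(counts, reverse=True)
    a = extract_cells(sm, DetectionParams())
    b = extract_cells(sm, DetectionParams())
    assert a == b
    assert [(c.y, c.x) for c in a] == sorted((c.y, c.x) for c in a)


@pytest.mark.parametrize("kwargs", [
    {"score_threshold": 0.0}, {"score_threshold": 1.5},
    {"min_region_area": 0}, {"cell_radius": -1},
])
def test_invalid_detection_params(kwargs):
    with pytest.raises(ValueError):
        DetectionParams(**kwargs)


# ---------------------------------------------------------------- training

def test_zero_epoch_budget_rejected():
    with pytest.raises(ValueError):
        DetectorTrainConfig(epochs=0)


def test_training_requires_positive_patches():
    img, _ = generate_scene(SceneSpec(width=128, height=128, seed=0))
    from er_allred.synthetic import SyntheticGroundTruth
    with pytest.raises(ValueError, match="no positive"):
        train_detector([img], [SyntheticGroundTruth([])])


def test_training_beats_constant_predictor(trained_detector, eval_scenes,
                                           synth_params):
    """Held-out MSE must undercut the variance of the target map, i.e. the
    trained regressor beats the best constant predictor."""
    img, truth = eval_scenes[0]
    target = build_score_target(truth.centroids, img.shape[:2],
                                synth_params.cell_radius)
    pred = predict_score_map(trained_detector, img)
    mse = float(np.mean((pred - target) ** 2))
    assert mse < float(np.var(target))


def test_training_is_reproducible():
    scenes = [make_scene(100 + i, width=128, height=128, n=(4, 2, 1, 1))
              for i in range(2)]
    cfg = DetectorTrainConfig(epochs=2, seed=5)
    arch = [{"type": "conv", "cin": 3, "cout": 4, "k": 3}, {"type": "relu"},
            {"type": "conv", "cin": 4, "cout": 1, "k": 3}]
    kwargs = dict(images=[s[0] for s in scenes], truths=[s[1] for s in scenes],
                  cfg=cfg, arch=arch)
    n1 = train_detector(**kwargs)
    n2 = train_detector(**kwargs)
    assert n1.meta["loss_history"] == n2.meta["loss_history"]


# ---------------------------------------------------------------- inference

def test_background_scene_scores_low(trained_detector):
    img, _ = generate_scene(SceneSpec(width=256, height=256, seed=900))
    sm = predict_score_map(trained_detector, img)
    assert np.mean(sm < 0.2) >= 0.99


def test_isolated_nucleus_peak_near_centroid(trained_detector, synth_params):
    img, truth = make_scene(901, width=160, height=160, n=(0, 0, 1, 0))
    sm = predict_score_map(trained_detector, img)
    cells = extract_cells(sm, synth_params)
    assert len(cells) == 1
    nuc = truth.nuclei[0]
    assert np.hypot(cells[0].x - nuc.x, cells[0].y - nuc.y) <= 8


def test_constant_image_gives_near_constant_map(trained_detector):
    img = np.full((96, 96, 3), 180, dtype=np.uint8)
    sm = predict_score_map(trained_detector, img)
    interior = sm[20:-20, 20:-20]  # away from zero-padding border effects
    assert float(interior.max() - interior.min()) < 1e-4


def test_image_below_receptive_field_rejected(trained_detector):
    tiny = np.zeros((8, 8, 3), dtype=np.uint8)
    with pytest.raises(ValueError, match="receptive field"):
        predict_score_map(trained_detector, tiny)
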