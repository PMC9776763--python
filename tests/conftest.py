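"""Shared fixtures: synthetic training data and session-trained models.

The synthetic study conditions are fixed here once: training fields of
256x256 px with ~25 nuclei each, evaluation fields of 448x448 px with 100
nuclei each at <= 10% overlap, and a score-target radius of 20 px matching
the nominal synthetic nucleus scale (major semi-axis 12-20 px). Both
networks are trained once per session at reduced epoch budgets.
"""

import numpy as np
import pytest

from er_allred import (DetectionParams, DetectorTrainConfig, WMSTrainConfig,
                       generate_patchset, generate_scene, train_detector,
                       train_wms)
from er_allred.synthetic import SceneSpec

#: score-target radius matched to the synthetic nucleus scale
SYNTH_PARAMS = DetectionParams(cell_radius=20.0)


def make_scene(seed, width=256, height=256, n=(10, 5, 5, 5), **kw):
    spec = SceneSpec(width=width, height=height, n_negative=n[0], n_weak=n[1],
                     n_moderate=n[2], n_strong=n[3], seed=seed, **kw)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def synth_params():
    return SYNTH_PARAMS


@pytest.fixture(scope="session")
def train_scenes():
    return [make_scene(100 + i) for i in range(6)]


@pytest.fixture(scope="session")
def eval_scenes():
    """Two held-out 448x448 fields, 100 nuclei each (<= 10% overlap)."""
    return [make_scene(200 + j, width=448, height=448, n=(50, 17, 17, 16))
            for j in range(2)]


@pytest.fixture(scope="session")
def trained_detector(train_scenes):
    images = [s[0] for s in train_scenes]
    truths = [s[1] for s in train_scenes]
    return train_detector(images, truths, SYNTH_PARAMS,
                          DetectorTrainConfig(epochs=8, seed=0))


@pytest.fixture(scope="session")
def trained_wms():
    patches, labels = generate_patchset(150, seed=11, classes=("W", "M", "S"))
    return train_wms(patches, labels, WMSTrainConfig(epochs=15, seed=1))


def centroid_array(cells):
    return np.array([[c.x, c.y] for c in cells], dtype=float).reshape(-1, 2)
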