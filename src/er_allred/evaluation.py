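"""Whole-field pipeline execution and evaluation metrics.

Covers tiling of large images into high-power-field-sized regions, the
end-to-end detect/classify/score pipeline for one slide, and the evaluation
statistics used to benchmark it: one-to-one centroid matching with
precision/recall, confusion-matrix metrics with optional exclusion of
spillover rows (negatives/non-tumor objects wrongly fed to a stage by its
predecessor), and slide-level agreement between manual and automated Allred
scores. Also exposes the packaged per-slide scoring reference table (40
slides: manual score components plus automated ER% and class proportions).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import nn
from .allred import AllredResult, SlideSummary, allred
from .detection import DetectedCell, DetectionParams, extract_cells, predict_score_map
from .stain import PNThresholds, classify_cells

__all__ = [
    "MatchResult",
    "AgreementStats",
    "tile_image",
    "run_slide",
    "match_detections",
    "detection_metrics",
    "confusion_metrics",
    "agreement_stats",
    "load_table8",
]


@dataclass(frozen=True)
class MatchResult:
    """One-to-one matching of predicted to true centroids."""

    tp: int
    fp: int
    fn: int
    pairs: tuple  # ((pred_idx, truth_idx), ...)


@dataclass(frozen=True)
class AgreementStats:
    """Slide-level agreement between two Allred score lists."""

    n: int
    exact: int
    diff_hist: dict  # |manual - automated| -> count; bins disjoint, sum to n
    treatment_agreements: int
    treatment_accuracy_pct: float


def tile_image(image: np.ndarray, field_size: int, overlap: int = 0) -> list:
    """Split an image into a grid of field-sized tiles with their offsets.

    Returns a list of (tile, (x_offset, y_offset)). With overlap 0 the grid
    is a partition: tiles are disjoint and cover every pixel once; partial
    edge tiles are included.
    """
    h, w = image.shape[:2]
    if field_size <= 0:
        raise ValueError("field_size must be > 0")
    if field_size > h or field_size > w:
        raise ValueError("field_size must not exceed the image size")
    if not 0 <= overlap < field_size:
        raise ValueError("overlap must be in [0, field_size)")
    step = field_size - overlap
    tiles = []
    for y0 in range(0, h, step):
        for x0 in range(0, w, step):
            tile = image[y0:min(y0 + field_size, h), x0:min(x0 + field_size, w)]
            tiles.append((tile, (x0, y0)))
    return tiles


def _merge_seam_duplicates(cells: list, tile_ids: list, radius: float) -> list:
    """Merge detections within `radius` px coming from different tiles."""
    if not cells:
        return []
    coords = np.array([[c.y, c.x] for c in cells])
    parent = list(range(len(cells)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    d = cdist(coords, coords)
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            if tile_ids[i] != tile_ids[j] and d[i, j] <= radius:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(cells)):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for idx in groups.values():
        xs = float(np.mean([cells[i].x for i in idx]))
        ys = float(np.mean([cells[i].y for i in idx]))
        area = float(np.mean([cells[i].area for i in idx]))
        merged.append(DetectedCell(xs, ys, area))
    merged.sort(key=lambda c: (c.y, c.x))
    return merged


def run_slide(image: np.ndarray, detector: nn.Network, wms_model: nn.Network,
              params: DetectionParams | None = None,
              pn_thresholds: PNThresholds | None = None,
              field_size: int = 512, merge_radius: float = 8.0
              ) -> tuple[list, SlideSummary, AllredResult]:
    """Full pipeline over one slide image.

    Detection runs tile by tile on high-power-field-sized regions; seam
    duplicates (detections within ``merge_radius`` px across adjacent tiles)
    are merged to their mean centroid. Classification and Allred scoring
    then run over the merged cell list. Deterministic for fixed inputs.
    """
    params = params or DetectionParams()
    h, w = image.shape[:2]
    fs = min(field_size, h, w)
    all_cells: list[DetectedCell] = []
    tile_ids: list[int] = []
    for tid, (tile, (x0, y0)) in enumerate(tile_image(image, fs)):
        if min(tile.shape[:2]) < detector.receptive_field():
            continue  # slivers below the receptive field carry no new cells
        sm = predict_score_map(detector, tile)
        for c in extract_cells(sm, params):
            all_cells.append(DetectedCell(c.x + x0, c.y + y0, c.area))
            tile_ids.append(tid)
    cells = _merge_seam_duplicates(all_cells, tile_ids, merge_radius)
    cells = classify_cells(image, cells, pn_thresholds, wms_model)
    summary = SlideSummary.from_cells(cells)
    return cells, summary, allred(summary)


def match_detections(predicted, truth, tol: float = 16.0) -> MatchResult:
    """Greedy one-to-one matching of predicted to true centroids.

    Candidate pairs are taken in ascending distance order (ties broken by
    indices); pairs farther than ``tol`` are rejected. Unmatched predictions
    count as false positives, unmatched truths as false negatives.
    """
    if tol <= 0:
        raise ValueError("matching tolerance must be > 0")
    pred = np.asarray(predicted, dtype=float).reshape(-1, 2)
    tru = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(pred) == 0 or len(tru) == 0:
        return MatchResult(0, len(pred), len(tru), ())
    d = cdist(pred, tru)
    order = np.argsort(d, axis=None, kind="stable")
    used_p = np.zeros(len(pred), dtype=bool)
    used_t = np.zeros(len(tru), dtype=bool)
    pairs = []
    for flat in order:
        i, j = divmod(int(flat), len(tru))
        if d[i, j] > tol:
            break
        if used_p[i] or used_t[j]:
            continue
        used_p[i] = used_t[j] = True
        pairs.append((i, j))
    tp = len(pairs)
    return MatchResult(tp, len(pred) - tp, len(tru) - tp, tuple(pairs))


def detection_metrics(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """(recall, precision) from detection counts."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    if tp + fn == 0:
        raise ValueError("recall undefined: no true cells (TP + FN = 0)")
    if tp + fp == 0:
        raise ValueError("precision undefined: no detections (TP + FP = 0)")
    return tp / (tp + fn), tp / (tp + fp)


def confusion_metrics(cm: pd.DataFrame, exclude_rows: Sequence[str] = ()
                      ) -> dict:
    """Accuracy and per-class PPV/TPR from a labeled confusion matrix.

    Rows are true labels (possibly including spillover rows such as
    Negative/Non-Tumor that have no matching predicted column), columns are
    predicted labels. ``exclude_rows`` drops spillover rows first, giving
    the only-true-cells variant. Accuracy is the sum of diagonal cells
    (row label == column label) over the grand total; PPV is per predicted
    column, TPR per true row that has a matching column.
    """
    if cm.size == 0:
        raise ValueError("empty confusion matrix")
    if (cm.values < 0).any():
        raise ValueError("confusion matrix entries must be >= 0")
    unknown = set(exclude_rows) - set(cm.index)
    if unknown:
        raise ValueError(f"exclude_rows not in matrix: {sorted(unknown)}")
    m = cm.drop(index=list(exclude_rows))
    total = float(m.values.sum())
    if total == 0:
        raise ValueError("confusion matrix sums to zero")
    diag = {c: float(m.at[c, c]) for c in m.columns if c in m.index}
    ppv = {c: (diag.get(c, 0.0) / s if (s := float(m[c].sum())) > 0 else np.nan)
           for c in m.columns}
    tpr = {c: (diag[c] / s if (s := float(m.loc[c].sum())) > 0 else np.nan)
           for c in m.columns if c in m.index}
    return {"accuracy": sum(diag.values()) / total, "ppv": ppv, "tpr": tpr}


def agreement_stats(manual: Sequence[int], automated: Sequence[int],
                    actionable_threshold: int = 3) -> AgreementStats:
    """Slide-level Allred agreement: exact matches, |difference| histogram,
    and hormonal-treatment concordance at the actionable cutoff."""
    manual = list(manual)
    automated = list(automated)
    if len(manual) != len(automated):
        raise ValueError("score lists must have equal length")
    valid = {0, 2, 3, 4, 5, 6, 7, 8}
    for s in (*manual, *automated):
        if s not in valid:
            raise ValueError(f"invalid Allred score {s}")
    diffs = [abs(a - b) for a, b in zip(manual, automated)]
    hist: dict[int, int] = {}
    for d in diffs:
        hist[d] = hist.get(d, 0) + 1
    agree = sum((a >= actionable_threshold) == (b >= actionable_threshold)
                for a, b in zip(manual, automated))
    n = len(manual)
    return AgreementStats(n=n, exact=hist.get(0, 0), diff_hist=hist,
                          treatment_agreements=agree,
                          treatment_accuracy_pct=100.0 * agree / n if n else 0.0)


def load_table8() -> pd.DataFrame:
    """The packaged 40-slide scoring reference table.

    Columns: manual ER status band, intensity and score components, plus the
    automated ER percentage, strong/moderate/weak proportions, and automated
    score components. The row flagged ``inconsistent_proportions`` has a
    class breakdown that does not sum to its ER percentage (a transcription
    artifact in the source) and is excluded from exact-reproduction checks.
    """
    with resources.files("er_allred.data").joinpath("table8.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"image_id": str}, keep_default_na=False)
    return df
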