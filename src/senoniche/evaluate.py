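"""Ground-truth recovery metrics for the synthetic benchmark.

These helpers compare pipeline outputs against planted truth: one-to-one
point matching for seed detection, pixel-level adjusted Rand index for
segmentation, and confusion summaries for reporter and type calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "match_points",
    "seed_precision_recall",
    "segmentation_ari",
    "reporter_confusion",
]


def match_points(
    detected: np.ndarray, truth: np.ndarray, max_dist: float
) -> pd.DataFrame:
    """Greedy one-to-one matching of detected points to true points.

    Candidate pairs within ``max_dist`` are matched in increasing distance
    order, each point used at most once. Returns columns
    ``detected_idx``, ``truth_idx``, ``dist``.
    """
    detected = np.atleast_2d(np.asarray(detected, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if len(detected) == 0 or len(truth) == 0:
        return pd.DataFrame(columns=["detected_idx", "truth_idx", "dist"])
    tree = cKDTree(truth)
    pairs = tree.query_ball_point(detected, r=max_dist)
    cand = [
        (float(np.hypot(*(detected[i] - truth[j]))), i, j)
        for i, js in enumerate(pairs)
        for j in js
    ]
    cand.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    rows = []
    for dist, i, j in cand:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        rows.append((i, j, dist))
    return pd.DataFrame(rows, columns=["detected_idx", "truth_idx", "dist"])


def seed_precision_recall(
    detected_xy: np.ndarray, truth_xy: np.ndarray, max_dist: float = 3.0
) -> tuple[float, float, pd.DataFrame]:
    """Precision and recall of detected seeds against true centroids."""
    matches = match_points(detected_xy, truth_xy, max_dist)
    n_match = len(matches)
    precision = n_match / len(detected_xy) if len(detected_xy) else 0.0
    recall = n_match / len(truth_xy) if len(truth_xy) else 0.0
    return precision, recall, matches


def segmentation_ari(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Pixel-level adjusted Rand index between two label images."""
    if labels_a.shape != labels_b.shape:
        raise ValueError("label images must share shape")
    return float(adjusted_rand_score(labels_a.ravel(), labels_b.ravel()))


def reporter_confusion(
    predicted_positive: pd.Series, truth_positive: pd.Series
) -> dict[str, float]:
    """Sensitivity and false-positive rate of p21 calls on matched cells."""
    pred = predicted_positive.astype(bool)
    truth = truth_positive.reindex(pred.index).astype(bool)
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "false_positive_rate": fp / (fp + tn) if fp + tn else float("nan"),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }
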