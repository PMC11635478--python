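"""Scoring detections and classifications against synthetic ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


def match_points(
    detected_xy: np.ndarray, true_xy: np.ndarray, radius: float = 3.0
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detections to truth by distance.

    Candidate pairs within ``radius`` are accepted in order of increasing
    distance; each detection and each truth entry is used at most once.
    """
    detected_xy = np.atleast_2d(np.asarray(detected_xy, dtype=float))
    true_xy = np.atleast_2d(np.asarray(true_xy, dtype=float))
    if detected_xy.size == 0 or true_xy.size == 0:
        return []
    tree = cKDTree(true_xy)
    pairs = []
    for di, neighbors in enumerate(tree.query_ball_point(detected_xy, r=radius)):
        for ti in neighbors:
            d = float(np.hypot(*(detected_xy[di] - true_xy[ti])))
            pairs.append((d, di, ti))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for _, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        matches.append((di, ti))
    return matches


def precision_recall(
    detected_xy: np.ndarray, true_xy: np.ndarray, radius: float = 3.0
) -> tuple[float, float, int]:
    """(precision, recall, #matches) of detections vs ground-truth positions."""
    detected_xy = np.atleast_2d(np.asarray(detected_xy, dtype=float))
    true_xy = np.atleast_2d(np.asarray(true_xy, dtype=float))
    n_det = 0 if detected_xy.size == 0 else len(detected_xy)
    n_true = 0 if true_xy.size == 0 else len(true_xy)
    matches = match_points(detected_xy, true_xy, radius)
    tp = len(matches)
    precision = tp / n_det if n_det else 1.0
    recall = tp / n_true if n_true else 1.0
    return precision, recall, tp


def interior_truth(
    truth: pd.DataFrame, shape: tuple[int, int], margin: float
) -> pd.DataFrame:
    """Truth particles away from the border (the detector excludes a margin)."""
    ny, nx = shape
    sel = (
        (truth["x_px"] >= margin)
        & (truth["x_px"] <= nx - margin)
        & (truth["y_px"] >= margin)
        & (truth["y_px"] <= ny - margin)
    )
    return truth.loc[sel]


def label_accuracy(
    particles_df: pd.DataFrame, truth: pd.DataFrame, radius: float = 3.0
) -> tuple[float, int]:
    """Fraction of matched particles whose 7-way label equals the truth category."""
    det_xy = particles_df[["x_px", "y_px"]].to_numpy()
    true_xy = truth[["x_px", "y_px"]].to_numpy()
    matches = match_points(det_xy, true_xy, radius)
    if not matches:
        return 0.0, 0
    det_labels = particles_df["label"].to_numpy()
    true_labels = truth["category"].to_numpy()
    correct = sum(det_labels[di] == true_labels[ti] for di, ti in matches)
    return correct / len(matches), len(matches)
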