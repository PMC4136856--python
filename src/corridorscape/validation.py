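"""Suitability-map validation against independent presence/absence points.

Implements the transect labelling rule (a segment counts as an absence only
if no sign was found there *and* no sign-bearing segment lies within 1 km;
otherwise ambiguous segments are dropped) and rank-based ROC/AUC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

ABSENCE_RADIUS_M = 1000.0


def assign_validation_labels(
    segments: pd.DataFrame, radius: float = ABSENCE_RADIUS_M
) -> pd.DataFrame:
    """Convert raw sign records to presence/absence validation labels.

    ``segments`` needs columns ``x``, ``y``, ``sign`` (0/1).  Presence =
    any sign at the segment.  Absence = no sign at the segment and no
    sign-bearing segment within ``radius`` meters.  No-sign segments near
    sign are ambiguous and dropped.  Returns the surviving rows with a
    ``label`` column (1 = presence, 0 = absence).
    """
    if len(segments) == 0:
        raise ValueError("empty segment table")
    xy = segments[["x", "y"]].to_numpy(dtype=float)
    sign = segments["sign"].to_numpy(dtype=int)
    pres_xy = xy[sign == 1]
    keep, labels = [], []
    for i in range(len(segments)):
        if sign[i] == 1:
            keep.append(i)
            labels.append(1)
            continue
        if pres_xy.size == 0:
            near = False
        else:
            d = np.hypot(pres_xy[:, 0] - xy[i, 0], pres_xy[:, 1] - xy[i, 1])
            near = bool((d <= radius).any())
        if not near:
            keep.append(i)
            labels.append(0)
        # else: ambiguous, dropped
    out = segments.iloc[keep].copy()
    out["label"] = labels
    return out


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC by the rank (Mann-Whitney) formulation, ties counted 1/2, plus
    the ROC point list at every distinct threshold.

    AUC is the probability that a random presence outscores a random
    absence; it is invariant to any strictly monotone transform of the
    scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # average ranks handle ties
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    s_sorted, l_sorted = scores[order], labels[order]
    pts = [(0.0, 0.0, np.inf)]
    tp = fp = 0
    i = 0
    while i < len(s_sorted):
        thr = s_sorted[i]
        while i < len(s_sorted) and s_sorted[i] == thr:
            tp += int(l_sorted[i] == 1)
            fp += int(l_sorted[i] == 0)
            i += 1
        pts.append((fp / n_neg, tp / n_pos, thr))
    roc = pd.DataFrame(pts, columns=["fpr", "tpr", "threshold"])
    return float(auc), roc


def validate_map(psi_map, segments: pd.DataFrame,
                 radius: float = ABSENCE_RADIUS_M) -> dict:
    """Label segments, read the suitability score at each, compute AUC."""
    labelled = assign_validation_labels(segments, radius)
    scores = np.array([
        psi_map.values[int(r), int(c)]
        for r, c in zip(labelled["row"], labelled["col"])
    ])
    auc, roc = roc_auc(scores, labelled["label"].to_numpy())
    return {
        "auc": auc,
        "n_presence": int((labelled["label"] == 1).sum()),
        "n_absence": int((labelled["label"] == 0).sum()),
        "n_dropped": len(segments) - len(labelled),
        "roc": roc,
    }
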