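"""Detection and segmentation accuracy metrics.

Detections are matched to ground-truth centres by *mutual* nearest
neighbours: a detection and a truth point match only when each is the
other's closest point (and they lie within ``max_dist``).  Matched pairs are
true positives; unmatched truths are false negatives; unmatched detections
are false positives.  From the counts:

    TP rate   = TP / (TP + FN)          (recall over ground truth)
    Precision = TP / (TP + FP)
    FN rate   = FN / (TP + FN)

Voxel-level accuracy is the Jaccard index J(R, S) = |R & S| / |R | S| of the
foreground voxel sets of the truth annotation R and the segmentation S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "MatchReport",
    "match_points",
    "compute_rates",
    "jaccard",
    "evaluate",
    "summarize_reports",
]


@dataclass
class MatchReport:
    """Counts, rates and matches of one segmentation-vs-truth comparison.

    Rates with an undefined denominator (e.g. precision with no detections)
    are ``None`` rather than 0, so aggregation can skip them explicitly.
    """

    tp: int
    fp: int
    fn: int
    tp_rate: float | None
    precision: float | None
    fn_rate: float | None
    matches: list[tuple[int, int, float]]  # (detection_id, truth_id, distance px)
    jaccard: float | None = None

    def __post_init__(self) -> None:
        if self.tp > min(self.tp + self.fp, self.tp + self.fn):
            raise ValueError("inconsistent match counts")
        for r in (self.tp_rate, self.precision, self.fn_rate, self.jaccard):
            if r is not None and not 0 <= r <= 1:
                raise ValueError(f"rate {r} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tp_rate": self.tp_rate,
            "precision": self.precision,
            "fn_rate": self.fn_rate,
            "jaccard": self.jaccard,
            "n_matches": len(self.matches),
        }


def match_points(
    detections: np.ndarray,
    truth: np.ndarray,
    max_dist: float,
) -> tuple[int, int, int, list[tuple[int, int, float]]]:
    """Mutual-nearest-neighbour matching of detections to truth centres.

    Both inputs are (n, d) coordinate arrays (any common dimension).  A pair
    matches iff each point is the other's nearest neighbour *and* their
    distance is at most ``max_dist``; each point participates in at most one
    match.  Nearest-neighbour ties resolve to the lowest index
    (deterministic).  Returns ``(tp, fp, fn, matches)``.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    det = np.atleast_2d(np.asarray(detections, dtype=float))
    tru = np.atleast_2d(np.asarray(truth, dtype=float))
    n_det = 0 if det.size == 0 else len(det)
    n_tru = 0 if tru.size == 0 else len(tru)
    if n_det == 0 or n_tru == 0:
        return 0, n_det, n_tru, []

    _, nn_of_det = cKDTree(tru).query(det)  # nearest truth per detection
    _, nn_of_tru = cKDTree(det).query(tru)  # nearest detection per truth
    matches = []
    for i in range(n_det):
        j = int(nn_of_det[i])
        if int(nn_of_tru[j]) != i:
            continue
        d = float(np.linalg.norm(det[i] - tru[j]))
        if d <= max_dist:
            matches.append((i, j, d))
    tp = len(matches)
    return tp, n_det - tp, n_tru - tp, matches


def compute_rates(
    tp: int, fp: int, fn: int
) -> tuple[float | None, float | None, float | None]:
    """TP rate, precision and FN rate from match counts.

    Undefined rates (zero denominator) come back as ``None``.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    tp_rate = tp / (tp + fn) if tp + fn > 0 else None
    precision = tp / (tp + fp) if tp + fp > 0 else None
    fn_rate = fn / (tp + fn) if tp + fn > 0 else None
    return tp_rate, precision, fn_rate


def jaccard(truth_labels: np.ndarray, seg_labels: np.ndarray) -> float:
    """Jaccard index of the two foreground voxel sets.

    Computed on binary foreground (any nonzero label), i.e. the voxel-level
    overlap of annotation and segmentation.  Symmetric in its arguments.
    """
    r = np.asarray(truth_labels) != 0
    s = np.asarray(seg_labels) != 0
    if r.shape != s.shape:
        raise ValueError(f"label grids differ in shape: {r.shape} vs {s.shape}")
    union = np.logical_or(r, s).sum()
    if union == 0:
        return 1.0  # both empty: perfect (vacuous) agreement
    return float(np.logical_and(r, s).sum() / union)


def evaluate(result, truth, max_dist: float) -> MatchReport:
    """Match a segmentation result against ground truth and compute rates.

    ``result`` needs a ``centroids`` (n, 3) property and optionally a
    ``label_volume``; ``truth`` needs ``centers`` and optionally a
    ``label_volume(dims)`` method or array (as from
    :mod:`wavenuc.synthetic`).  ``max_dist`` is the matching cap in pixels —
    conventionally the nucleus radius.
    """
    det = np.asarray(result.centroids, dtype=float)
    tru = np.asarray(truth.centers, dtype=float)
    tp, fp, fn, matches = match_points(det, tru, max_dist)
    tp_rate, precision, fn_rate = compute_rates(tp, fp, fn)

    jac = None
    seg_lab = getattr(result, "label_volume", None)
    if seg_lab is not None:
        truth_lab = getattr(truth, "label_volume", None)
        if callable(truth_lab):
            nz, ny, nx = np.asarray(seg_lab).shape
            truth_lab = truth_lab((nx, ny, nz))
        if truth_lab is not None:
            jac = jaccard(truth_lab, seg_lab)

    return MatchReport(
        tp=tp, fp=fp, fn=fn,
        tp_rate=tp_rate, precision=precision, fn_rate=fn_rate,
        matches=matches, jaccard=jac,
    )


def summarize_reports(reports: list[MatchReport]) -> pd.DataFrame:
    """Mean and standard deviation of each metric over a batch of volumes.

    Undefined (``None``) rates are excluded per metric.  Returns a DataFrame
    indexed by metric with columns ``mean``, ``std`` and ``n``.
    """
    rows = {}
    for name in ("tp_rate", "precision", "fn_rate", "jaccard"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        rows[name] = {
            "mean": float(np.mean(vals)) if vals else np.nan,
            "std": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0 if vals else np.nan,
            "n": len(vals),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
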