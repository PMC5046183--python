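"""Detection evaluation: point matching, P/R/F, PR curves, AUC, group tests.

A detection is a true positive if it can be paired one-to-one with a
ground-truth nucleus centre within a matching radius (15 px by default,
about 3.68 um at 0.2455 um/pixel). Matching is greedy nearest-first:
candidate pairs are sorted by distance and accepted whenever both endpoints
are still free. The precision-recall curve is traced by sweeping the global
vote threshold T_D over a fixed grid (0 to 1, step 0.05), pooling counts
over all images of a cohort; its area is the trapezoidal integral over the
observed recall values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .seeds import SeedSet, extract_seeds

__all__ = [
    "GroundTruth",
    "EvalReport",
    "BENCHMARK_COHORTS",
    "default_grid",
    "match",
    "rates",
    "pr_curve",
    "per_image_auc",
    "radius_in_um",
    "compare_methods",
]

#: Published benchmark cohorts this evaluation protocol was designed around:
#: breast H&E, breast CD31 & hematoxylin, skin Ki-67, breast H&E tiles at
#: ~0.25 um/pixel with manually labelled nucleus centres.
BENCHMARK_COHORTS = pd.DataFrame(
    {
        "name": ["A", "B", "C", "D"],
        "site": ["breast", "breast", "skin", "breast"],
        "stain": ["H&E", "CD31&H", "Ki-67", "H&E"],
        "resolution_um_per_px": [0.2455, 0.2514, 0.2475, 0.2455],
        "n_images": [12, 10, 5, 21],
        "n_nuclei": [4598, 5248, 1998, 5859],
    }
)


@dataclass
class GroundTruth:
    """Manually labelled nucleus centres for one image."""

    centers: np.ndarray  # (N, 2) float, (x, y)
    image_id: str = ""
    resolution_um_per_px: float = 0.2455

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution must be positive")

    def __len__(self) -> int:
        return len(self.centers)

    @classmethod
    def from_csv(cls, path, image_id: str = "", resolution_um_per_px: float = 0.2455):
        df = pd.read_csv(path)
        return cls(df[["x", "y"]].to_numpy(dtype=float), image_id, resolution_um_per_px)

    def to_csv(self, path) -> None:
        pd.DataFrame({"x": self.centers[:, 0], "y": self.centers[:, 1]}).to_csv(
            path, index=False
        )


@dataclass
class EvalReport:
    n_gt: int
    n_det: int
    n_tp: int
    n_fp: int
    n_fn: int
    precision: float
    recall: float
    f_measure: float
    prc: List[Tuple[float, float]] = field(default_factory=list)  # (recall, precision)
    auc: float = float("nan")
    thresholds: List[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_gt": self.n_gt,
            "n_det": self.n_det,
            "n_tp": self.n_tp,
            "n_fp": self.n_fp,
            "n_fn": self.n_fn,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "prc": [list(p) for p in self.prc],
            "auc": self.auc,
            "thresholds": list(self.thresholds),
        }


def default_grid(step: float = 0.05) -> np.ndarray:
    """The T_D sweep grid: 0 to 1 inclusive at the given resolution."""
    n = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, n + 1)


def _centers(obj) -> np.ndarray:
    if isinstance(obj, (SeedSet, GroundTruth)):
        return obj.centers
    return np.asarray(obj, dtype=float).reshape(-1, 2)


def match(det, gt, radius_px: float = 15.0) -> Tuple[int, int, int]:
    """Greedy one-to-one matching of detections to ground truth.

    All (det, gt) pairs within ``radius_px`` are sorted by ascending distance
    (ties by detection index, then ground-truth index, for determinism) and
    accepted while both endpoints are unmatched. Returns (n_tp, n_fp, n_fn).
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    d = _centers(det)
    g = _centers(gt)
    if len(d) == 0 or len(g) == 0:
        return 0, len(d), len(g)
    dist = cdist(d, g)
    di, gi = np.nonzero(dist <= radius_px)
    dd = dist[di, gi]
    order = np.lexsort((gi, di, dd))
    det_free = np.ones(len(d), dtype=bool)
    gt_free = np.ones(len(g), dtype=bool)
    tp = 0
    for k in order:
        i, j = di[k], gi[k]
        if det_free[i] and gt_free[j]:
            det_free[i] = False
            gt_free[j] = False
            tp += 1
    return tp, len(d) - tp, len(g) - tp


def rates(n_tp: int, n_fp: int, n_gt: int) -> Tuple[float, float, float]:
    """Precision, recall and F-measure from matched counts.

    Precision is 0 when there are no detections; F is 0 when P + R = 0.
    Recall is undefined without ground truth (n_gt must be >= 1).
    """
    if min(n_tp, n_fp) < 0:
        raise ValueError("counts must be nonnegative")
    if n_gt < 1:
        raise ValueError("recall undefined for n_gt = 0")
    n_det = n_tp + n_fp
    precision = n_tp / n_det if n_det > 0 else 0.0
    recall = n_tp / n_gt
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f


def _auc_from_points(points: Sequence[Tuple[float, float]]) -> float:
    """Trapezoid over observed (recall, precision) points, sorted by recall."""
    if len(points) < 2:
        return 0.0
    pts = sorted(points)
    r = np.array([p[0] for p in pts])
    p = np.array([p[1] for p in pts])
    return float(np.trapezoid(p, r))


def pr_curve(
    vote_maps: Sequence[np.ndarray],
    gts: Sequence[GroundTruth],
    grid: Optional[Sequence[float]] = None,
    radius_px: float = 15.0,
    min_area: int = 1,
) -> EvalReport:
    """Pooled (micro-averaged) precision-recall curve over a set of images.

    For each grid threshold, seeds are extracted from every vote map and the
    TP/FP/GT counts pooled before computing one (recall, precision) point.
    At thresholds where no image yields any detection, precision is taken as
    1 (the empty-detection limit of the curve). The report's scalar P/R/F
    are those of the best-F point on the curve; AUC is the trapezoid over
    the observed recall values.
    """
    if len(vote_maps) != len(gts):
        raise ValueError("need one ground truth per vote map")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    n_gt_total = sum(len(g) for g in gts)
    if n_gt_total == 0:
        raise ValueError("no ground-truth nuclei")
    prc: List[Tuple[float, float]] = []
    per_t = []
    for t in grid:
        tp = fp = 0
        for v, g in zip(vote_maps, gts):
            s = extract_seeds(v, float(t), min_area=min_area)
            tpi, fpi, _ = match(s, g, radius_px)
            tp += tpi
            fp += fpi
        n_det = tp + fp
        recall = tp / n_gt_total
        precision = tp / n_det if n_det > 0 else 1.0
        prc.append((recall, precision))
        per_t.append((tp, fp, n_det))
    f_vals = [
        2 * p * r / (p + r) if (p + r) > 0 and (tp_ + fp_) > 0 else 0.0
        for (r, p), (tp_, fp_, _) in zip(prc, per_t)
    ]
    best = int(np.argmax(f_vals))
    tp_b, fp_b, ndet_b = per_t[best]
    p_b, r_b, f_b = rates(tp_b, fp_b, n_gt_total)
    return EvalReport(
        n_gt=n_gt_total,
        n_det=ndet_b,
        n_tp=tp_b,
        n_fp=fp_b,
        n_fn=n_gt_total - tp_b,
        precision=p_b,
        recall=r_b,
        f_measure=f_b,
        prc=prc,
        auc=_auc_from_points(prc),
        thresholds=[float(t) for t in grid],
    )


def per_image_auc(
    vote_map: np.ndarray,
    gt: GroundTruth,
    grid: Optional[Sequence[float]] = None,
    radius_px: float = 15.0,
    min_area: int = 1,
) -> float:
    """AUC of a single image's own PR curve (for per-image statistics)."""
    return pr_curve([vote_map], [gt], grid=grid, radius_px=radius_px, min_area=min_area).auc


def radius_in_um(radius_px: float, resolution_um_per_px: float) -> float:
    """Matching radius in micrometres."""
    if radius_px < 0 or resolution_um_per_px <= 0:
        raise ValueError("inputs must be positive")
    return radius_px * resolution_um_per_px


def compare_methods(
    aucs_a: Sequence[float],
    aucs_b: Sequence[float],
    equal_var: bool = True,
    alpha: float = 0.05,
) -> Tuple[float, float, bool]:
    """Two-sample t-test between two methods' per-image AUCs.

    Student's equal-variance form by default (``equal_var=False`` for
    Welch). Returns (t, p, significant-at-alpha). Two identical constant
    groups have no evidence of a difference: p = 1 by convention.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(p):
        t, p = 0.0, 1.0
    return float(t), float(p), bool(p < alpha)
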