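"""Seed extraction: vote image -> nucleus-centre detections.

A global threshold T_D (Otsu's method by default) binarises the normalised
vote image; the centroid of each 8-connected above-threshold component is a
detected nucleus centre. Binarisation uses the strict inequality v > T_D so
that T_D = 1 on a max-normalised map yields zero detections, giving the
precision-recall sweep a well-defined empty endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

__all__ = ["SeedSet", "otsu_threshold", "extract_seeds"]


@dataclass
class SeedSet:
    """Detected nucleus centres with their mean vote scores."""

    centers: np.ndarray  # (N, 2) float, (x, y)
    scores: np.ndarray  # (N,) mean vote value per component
    threshold: float

    def __len__(self) -> int:
        return len(self.centers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.centers[:, 0] if len(self) else [],
                "y": self.centers[:, 1] if len(self) else [],
                "score": self.scores if len(self) else [],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SeedSet":
        df = pd.read_csv(path)
        centers = df[["x", "y"]].to_numpy(dtype=float)
        scores = (
            df["score"].to_numpy(dtype=float)
            if "score" in df
            else np.ones(len(df))
        )
        return cls(centers=centers, scores=scores, threshold=float("nan"))


def otsu_threshold(v_n: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold of a [0, 1] vote image over a fixed 256-bin histogram.

    The histogram is taken over the fixed range [0, 1] (not the data range)
    so the threshold lives on the same scale as the T_D sweep grid. Returns
    the boundary (upper edge) of the background class at the split
    maximising the between-class variance, so ``v > T_D`` separates the two
    classes; a constant image returns that constant (no detections above
    it, by strict binarisation).
    """
    v = np.asarray(v_n, dtype=float).ravel()
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return hi
    counts, edges = np.histogram(v, bins=nbins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(counts)  # class-0 weight for threshold after bin i
    w1 = w0[-1] - w0
    mass = np.cumsum(counts * centers)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mass / w0
        mu1 = (mass[-1] - mass) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between[:-1], nan=-1.0)
    return float(edges[int(np.argmax(var_between)) + 1])


def extract_seeds(v_n: np.ndarray, t_d: float, min_area: int = 1) -> SeedSet:
    """Threshold the vote image and return one seed per connected component.

    Components are 8-connected; each seed sits at the pixel-coordinate
    centroid of its component, scored by the component's mean vote value.
    Seeds are ordered by their component's top-left-most pixel (row-major).
    Components smaller than ``min_area`` pixels are dropped.
    """
    v = np.asarray(v_n, dtype=float)
    if not (0.0 <= t_d <= 1.0):
        raise ValueError("t_d must lie in [0, 1]")
    binary = v > t_d
    labels = measure.label(binary, connectivity=2)
    centers, scores, order_keys = [], [], []
    w = v.shape[1]
    for lab in range(1, labels.max() + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(xs) < min_area:
            continue
        centers.append((xs.mean(), ys.mean()))
        scores.append(v[ys, xs].mean())
        order_keys.append(ys[0] * w + xs[0])
    if not centers:
        return SeedSet(np.empty((0, 2)), np.empty(0), float(t_d))
    order = np.argsort(order_keys, kind="stable")
    return SeedSet(
        centers=np.asarray(centers, dtype=float)[order],
        scores=np.asarray(scores, dtype=float)[order],
        threshold=float(t_d),
    )
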