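"""Gradient-field refinement via convex-hull symmetry of edge fragments.

Unevenly stained nuclei develop pale ("hollow") cores whose inner edge
contour carries inverse gradients pointing *away* from the nucleus — in
crowded regions these cast spurious votes between nuclei. Each connected
edge fragment is summarised by the centroid of its filled convex hull; an
edge pixel whose inverse gradient deviates from the pixel-to-centroid
bearing by more than ``theta_max`` (default pi/2) is labelled invalid.
Two refinement strategies deal with invalid pixels:

* GS1 — suppress them (zero their vectors, removing them from the vote);
* GS2 — reverse them (negate the vectors, so they vote inward instead).

Valid pixels always keep their original vector; for a contour of a solid
convex object every pixel is valid and refinement is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .gradients import VectorField

__all__ = [
    "EdgeFragment",
    "RefinedField",
    "extract_fragments",
    "hull_centroid",
    "angle_difference",
    "label_pixels",
    "refine",
]


@dataclass
class EdgeFragment:
    """One 8-connected component of the edge mask.

    ``xs``/``ys`` are the fragment's pixel coordinates (x = column, y = row)
    in row-major scan order. ``theta`` and ``valid`` are filled by
    :func:`label_pixels`.
    """

    index: int
    xs: np.ndarray
    ys: np.ndarray
    hull_vertices: Optional[np.ndarray] = None  # (M, 2) (x, y), or None if degenerate
    centroid: Optional[tuple] = None
    theta: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None
    _extra: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.xs)


@dataclass
class RefinedField:
    """A vector field after refinement with strategy 'none', 'gs1' or 'gs2'."""

    field: VectorField
    strategy: str


def extract_fragments(edge_mask: np.ndarray, min_size: int = 1) -> List[EdgeFragment]:
    """Split the edge mask into 8-connected fragments.

    Fragments are ordered by their top-left-most pixel (row-major scan) and
    indexed from 0. Fragments with fewer than ``min_size`` pixels are dropped.
    """
    edge_mask = np.asarray(edge_mask, dtype=bool)
    labels = measure.label(edge_mask, connectivity=2)
    frags: List[EdgeFragment] = []
    for lab in range(1, labels.max() + 1):
        ys, xs = np.nonzero(labels == lab)  # row-major order
        if len(xs) < min_size:
            continue
        frags.append(EdgeFragment(index=len(frags), xs=xs, ys=ys))
    # skimage labels in scan order already; sort defensively by first pixel
    frags.sort(key=lambda f: (f.ys[0], f.xs[0]))
    for i, f in enumerate(frags):
        f.index = i
    return frags


def _polygon_area_centroid(verts: np.ndarray):
    """Area and centroid of a simple polygon (shoelace); verts (M, 2) ordered."""
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return 0.0, tuple(verts.mean(axis=0))
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return a, (cx, cy)


def hull_centroid(frag: EdgeFragment) -> tuple:
    """Centroid of the filled convex hull of the fragment's pixels.

    For fewer than three non-collinear pixels the hull is degenerate and the
    arithmetic mean of the pixel coordinates is returned instead. The hull
    vertices (when they exist) are stored on the fragment.
    """
    if len(frag) == 0:
        raise ValueError("empty fragment has no centroid")
    pts = np.column_stack([frag.xs, frag.ys]).astype(float)
    centroid = None
    if len(pts) >= 3:
        try:
            hull = ConvexHull(pts)
            verts = pts[hull.vertices]  # counter-clockwise order
            frag.hull_vertices = verts
            _, centroid = _polygon_area_centroid(verts)
        except QhullError:
            pass  # collinear: fall through to the mean
    if centroid is None:
        frag.hull_vertices = None
        centroid = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
    frag.centroid = centroid
    return centroid


def angle_difference(p, c, g: VectorField) -> float:
    """Angle in [0, pi] between the p->c bearing and the inverse gradient at p.

    ``p`` is a pixel (x, y) on the support of ``g``; ``c`` the fragment's hull
    centroid. If p coincides with c the angle is defined as 0 (the gradient
    trivially points "toward" the centroid).
    """
    px, py = p
    vx, vy = c[0] - px, c[1] - py
    norm = float(np.hypot(vx, vy))
    if norm == 0.0:
        return 0.0
    gx = g.gx[int(py), int(px)]
    gy = g.gy[int(py), int(px)]
    dot = (vx * gx + vy * gy) / norm
    return float(np.arccos(np.clip(dot, -1.0, 1.0)))


def label_pixels(
    frag: EdgeFragment, g: VectorField, theta_max: float = np.pi / 2
) -> np.ndarray:
    """Label each fragment pixel valid (theta <= theta_max) or invalid.

    A pixel whose inverse gradient points toward the hull centroid contributes
    positively to the symmetry vote and is kept; one pointing away would vote
    outside the nucleus. The boundary case (exactly perpendicular, under the
    default theta_max = pi/2) is labelled valid. Pixels with a zero vector
    (flat-gradient edge pixels) get theta = pi/2 and cast no vote regardless.
    """
    c = frag.centroid if frag.centroid is not None else hull_centroid(frag)
    vx = c[0] - frag.xs
    vy = c[1] - frag.ys
    norm = np.hypot(vx, vy)
    gx = g.gx[frag.ys, frag.xs]
    gy = g.gy[frag.ys, frag.xs]
    with np.errstate(invalid="ignore", divide="ignore"):
        dot = np.where(norm > 0, (vx * gx + vy * gy) / np.where(norm > 0, norm, 1.0), 1.0)
    theta = np.arccos(np.clip(dot, -1.0, 1.0))
    frag.theta = theta
    frag.valid = theta <= theta_max + 1e-12
    return frag.valid


def refine(
    g: VectorField, fragments: List[EdgeFragment], strategy: str = "gs2"
) -> RefinedField:
    """Apply a refinement strategy to the edge-masked inverse-gradient field.

    ``none`` returns the field unchanged; ``gs1`` zeroes invalid pixels;
    ``gs2`` negates them. Fragments without labels are labelled on the fly
    with the default threshold.
    """
    strategy = strategy.lower()
    if strategy not in ("none", "gs1", "gs2"):
        raise ValueError(f"unknown refinement strategy {strategy!r}")
    out = g.copy()
    if strategy == "none":
        return RefinedField(out, strategy)
    for frag in fragments:
        if frag.valid is None:
            label_pixels(frag, g)
        bad = ~frag.valid
        if not bad.any():
            continue
        ys, xs = frag.ys[bad], frag.xs[bad]
        if strategy == "gs1":
            out.gx[ys, xs] = 0.0
            out.gy[ys, xs] = 0.0
        else:  # gs2
            out.gx[ys, xs] = -out.gx[ys, xs]
            out.gy[ys, xs] = -out.gy[ys, xs]
    return RefinedField(out, strategy)
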