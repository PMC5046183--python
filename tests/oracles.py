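"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity with the most naive method
available (exhaustive loops, closed forms, optimal assignment) and share no
code with the package beyond parameter values.
"""

import math

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist


def brute_force_votes(shape, xs, ys, alphas, r_min, r_max, sigma, sigma_radial, delta):
    """All-pairs fan voting: every voter x every raster pixel, tested directly."""
    h, w = shape
    v = np.zeros((h, w))
    mid = (r_min + r_max) / 2.0
    for x0, y0, a in zip(xs, ys, alphas):
        cx = x0 + mid * math.cos(a)
        cy = y0 + mid * math.sin(a)
        ca, sa = math.cos(a), math.sin(a)
        for qy in range(h):
            for qx in range(w):
                dxq, dyq = qx - x0, qy - y0
                r = math.hypot(dxq, dyq)
                if r < r_min or r > r_max:
                    continue
                d = math.atan2(dyq, dxq) - a
                dev = math.atan2(math.sin(d), math.cos(d))
                if abs(dev) > delta:
                    continue
                ex, ey = qx - cx, qy - cy
                d_par = ex * ca + ey * sa
                d_perp = -ex * sa + ey * ca
                v[qy, qx] += math.exp(
                    -(d_par**2) / (2 * sigma_radial**2) - d_perp**2 / (2 * sigma**2)
                )
    return v


def brute_force_otsu(values, nbins=256):
    """Exhaustive between-class-variance search over all histogram splits."""
    counts, edges = np.histogram(np.ravel(values), bins=nbins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    best_var, best_t = -1.0, edges[1]
    for i in range(nbins - 1):  # split after bin i; threshold = class boundary
        w0 = counts[: i + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: i + 1] * centers[: i + 1]).sum() / w0
        mu1 = (counts[i + 1 :] * centers[i + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, edges[i + 1]
    return float(best_t)


def optimal_match_tp(det, gt, radius):
    """Maximum-cardinality one-to-one matching within the radius (Hungarian)."""
    det = np.asarray(det, float).reshape(-1, 2)
    gt = np.asarray(gt, float).reshape(-1, 2)
    if len(det) == 0 or len(gt) == 0:
        return 0
    dist = cdist(det, gt)
    cost = np.where(dist <= radius, dist, 1e6)
    ri, ci = linear_sum_assignment(cost)
    return int((dist[ri, ci] <= radius).sum())


def filled_hull_centroid(points):
    """Centroid of the rasterised filled convex hull (fine supersampling)."""
    from scipy.spatial import ConvexHull
    from matplotlib.path import Path

    pts = np.asarray(points, float)
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]
    xmin, ymin = verts.min(axis=0) - 1
    xmax, ymax = verts.max(axis=0) + 1
    step = 0.05
    gx, gy = np.meshgrid(
        np.arange(xmin, xmax, step), np.arange(ymin, ymax, step)
    )
    inside = Path(verts).contains_points(np.column_stack([gx.ravel(), gy.ravel()]))
    sel = np.column_stack([gx.ravel(), gy.ravel()])[inside]
    return sel.mean(axis=0)
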