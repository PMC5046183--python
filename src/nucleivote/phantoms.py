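"""Synthetic phantom images with exact ground truth.

Three constructions mirror the regimes the detector must handle:

* solid convex nuclei (dark anti-aliased disks on a bright background);
* hollow-interior nuclei (dark annuli around a pale core) whose inner
  contour carries outward inverse gradients — the refinement target;
* a cluster of hollow nuclei whose central void collects the outward
  inner-contour votes of all members, the classic false-positive trap for
  unrefined voting.

Rasterisation is 4x super-sampled so edges are anti-aliased and Canny
yields clean single-pixel contours. Default intensities (background 220,
nucleus 90, hollow core 200, additive Gaussian noise sigma 3) emulate pale
hollow cores in an otherwise well-contrasted tile. All generators are
deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .evaluate import GroundTruth

__all__ = [
    "Nucleus",
    "PhantomSpec",
    "make_solid_disks",
    "make_hollow_nuclei",
    "make_hollow_cluster",
    "random_disk_spec",
]

SUPERSAMPLE = 4


@dataclass
class Nucleus:
    center: Tuple[float, float]  # (x, y)
    radius: float
    thickness: Optional[float] = None  # None = solid disk; else annulus ring width


@dataclass
class PhantomSpec:
    height: int = 200
    width: int = 200
    nuclei: List[Nucleus] = field(default_factory=list)
    background: float = 220.0
    foreground: float = 90.0
    core: float = 200.0  # hollow-core intensity
    noise_sigma: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        for n in self.nuclei:
            if n.radius < 3:
                raise ValueError("nucleus radius must be >= 3 px")
            x, y = n.center
            if not (n.radius <= x <= self.width - 1 - n.radius) or not (
                n.radius <= y <= self.height - 1 - n.radius
            ):
                raise ValueError(f"nucleus at {n.center} not fully inside image")
        for v in (self.background, self.foreground, self.core):
            if not (0 <= v <= 255):
                raise ValueError("intensities must lie in [0, 255]")


def _render(spec: PhantomSpec) -> Tuple[np.ndarray, GroundTruth]:
    """Rasterise the spec: supersample, paint, downsample, add noise."""
    s = SUPERSAMPLE
    hh, ww = spec.height * s, spec.width * s
    # sub-pixel sample coordinates in pixel units
    ys = (np.arange(hh) + 0.5) / s - 0.5
    xs = (np.arange(ww) + 0.5) / s - 0.5
    xg, yg = np.meshgrid(xs, ys)
    canvas = np.full((hh, ww), spec.background, dtype=float)
    for n in spec.nuclei:
        d = np.hypot(xg - n.center[0], yg - n.center[1])
        if n.thickness is None:
            canvas[d <= n.radius] = spec.foreground
        else:
            canvas[(d <= n.radius) & (d > n.radius - n.thickness)] = spec.foreground
            canvas[d <= n.radius - n.thickness] = spec.core
    img = canvas.reshape(spec.height, s, spec.width, s).mean(axis=(1, 3))
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    rgb = np.repeat(img8[:, :, None], 3, axis=2)
    gt = GroundTruth(
        centers=np.array([n.center for n in spec.nuclei], dtype=float).reshape(-1, 2)
    )
    return rgb, gt


def make_solid_disks(spec: PhantomSpec) -> Tuple[np.ndarray, GroundTruth]:
    """Dark solid disks on a bright background; ground truth = disk centres."""
    spec.validate()
    if any(n.thickness is not None for n in spec.nuclei):
        raise ValueError("solid-disk phantom must not contain annuli")
    return _render(spec)


def make_hollow_nuclei(spec: PhantomSpec) -> Tuple[np.ndarray, GroundTruth]:
    """Dark annuli with a pale core; each yields an outer and an inner contour."""
    spec.validate()
    for n in spec.nuclei:
        if n.thickness is None:
            raise ValueError("hollow phantom requires a ring thickness per nucleus")
        if n.thickness >= n.radius:
            raise ValueError("ring thickness must be smaller than the outer radius")
    return _render(spec)


def make_hollow_cluster(
    k: int = 3,
    center: Tuple[float, float] = (96.0, 96.0),
    circumradius: float = 31.0,
    radius: float = 15.0,
    thickness: float = 4.5,
    height: int = 192,
    width: int = 192,
    background: float = 210.0,
    ring: float = 200.0,
    core: float = 255.0,
    noise_sigma: float = 3.0,
    seed: int = 0,
) -> Tuple[np.ndarray, GroundTruth]:
    """A cluster of k poorly stained hollow nuclei around a central void.

    Emulates the classic false-positive trap of symmetry voting: unevenly
    stained nuclei whose pale core produces a strong *inner* contour with
    outward inverse gradients, while the washed-out outer boundary (ring
    barely darker than background) falls below the edge detector's
    hysteresis thresholds. Unrefined voting then sees only outward
    gradients, whose fans converge on the inter-nucleus void — the default
    geometry puts the void at the voting kernel's preferred range, about
    (r_min + r_max)/2 from the inner contours — yielding a spurious
    detection there and none at the true centres. Reversing the invalid
    gradients (GS2) redirects those votes onto the nuclei themselves.

    The nuclei sit on a circle of radius ``circumradius`` around ``center``
    (equilateral triangle for k = 3).
    """
    if k < 3:
        raise ValueError("cluster needs at least 3 nuclei")
    angles = -np.pi / 2 + 2 * np.pi * np.arange(k) / k
    nuclei = [
        Nucleus(
            center=(
                center[0] + circumradius * np.cos(a),
                center[1] + circumradius * np.sin(a),
            ),
            radius=radius,
            thickness=thickness,
        )
        for a in angles
    ]
    spec = PhantomSpec(
        height=height,
        width=width,
        nuclei=nuclei,
        background=background,
        foreground=ring,
        core=core,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    # pre-condition: neighbouring centres closer than twice the default r_max
    d = 2 * circumradius * np.sin(np.pi / k)
    if d >= 80:
        raise ValueError("cluster too loose: inter-centre gaps must be < 2 * r_max")
    return make_hollow_nuclei(spec)


def random_disk_spec(
    n: int,
    height: int = 256,
    width: int = 256,
    radius_range: Tuple[float, float] = (10.0, 16.0),
    min_gap: float = 5.0,
    noise_sigma: float = 3.0,
    seed: int = 0,
    max_tries: int = 10_000,
) -> PhantomSpec:
    """Place n non-overlapping solid disks at random.

    Pairwise centre distances are kept >= r_i + r_j + min_gap; raises if the
    image cannot accommodate the request within ``max_tries`` draws.
    """
    rng = np.random.default_rng(seed)
    nuclei: List[Nucleus] = []
    tries = 0
    while len(nuclei) < n:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n} non-overlapping disks in {width}x{height}"
            )
        tries += 1
        r = rng.uniform(*radius_range)
        margin = r + 2
        x = rng.uniform(margin, width - 1 - margin)
        y = rng.uniform(margin, height - 1 - margin)
        if all(
            np.hypot(x - m.center[0], y - m.center[1]) >= r + m.radius + min_gap
            for m in nuclei
        ):
            nuclei.append(Nucleus(center=(x, y), radius=r))
    return PhantomSpec(
        height=height,
        width=width,
        nuclei=nuclei,
        noise_sigma=noise_sigma,
        seed=seed + 1,  # rendering noise stream distinct from placement stream
    )
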