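"""Gradient field generation: smoothed channel, Canny edges, masked inverse gradient.

The voting stage consumes only the *direction* of the inverse intensity
gradient (for dark nuclei on a bright background it points from the nuclear
boundary into the nucleus), restricted to Canny edge pixels. Vectors are
therefore normalised to unit length and zeroed off the edge set.

Coordinate convention throughout the package: x = column, y = row, 0-based;
angles are measured from the +x axis counter-clockwise in image coordinates
(y pointing down).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import feature

__all__ = ["VectorField", "smooth", "inverse_gradient", "detect_edges", "mask_gradient"]

#: raw gradient magnitudes below this are treated as undefined (flat region)
EPS_MAGNITUDE = 1e-12


@dataclass
class VectorField:
    """Paired rasters holding the x/y components of a unit-vector field.

    Nonzero vectors are unit-norm; zeros mark pixels where the field is
    undefined (flat regions) or masked out (off the edge set).
    """

    gx: np.ndarray
    gy: np.ndarray

    def __post_init__(self) -> None:
        self.gx = np.asarray(self.gx, dtype=float)
        self.gy = np.asarray(self.gy, dtype=float)
        if self.gx.shape != self.gy.shape:
            raise ValueError("gx and gy must have identical shapes")

    @property
    def shape(self):
        return self.gx.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.gx, self.gy)

    def support(self) -> np.ndarray:
        """Boolean mask of pixels carrying a (unit) vector."""
        return self.magnitude() > 0

    def copy(self) -> "VectorField":
        return VectorField(self.gx.copy(), self.gy.copy())


def smooth(channel: np.ndarray, sigma_gau: float) -> np.ndarray:
    """Gaussian-smooth the scalar channel (reflective boundaries)."""
    if sigma_gau <= 0:
        raise ValueError("sigma_gau must be positive")
    return ndi.gaussian_filter(np.asarray(channel, dtype=float), sigma_gau, mode="reflect")


def inverse_gradient(i_s: np.ndarray) -> VectorField:
    """Unit inverse-gradient field of a smoothed image.

    Central differences give the intensity gradient; the field is its
    negation, normalised to unit length wherever the raw magnitude exceeds
    ``EPS_MAGNITUDE`` and zero elsewhere. For a dark object on a bright
    background the result points into the object.
    """
    i_s = np.asarray(i_s, dtype=float)
    if not np.all(np.isfinite(i_s)):
        raise ValueError("image must be finite")
    dy, dx = np.gradient(i_s)
    gx, gy = -dx, -dy
    mag = np.hypot(gx, gy)
    keep = mag > EPS_MAGNITUDE
    inv = np.where(keep, mag, 1.0)
    return VectorField(np.where(keep, gx / inv, 0.0), np.where(keep, gy / inv, 0.0))


def detect_edges(
    i_s: np.ndarray,
    low: float = 0.1,
    high: float = 0.3,
    canny_sigma: float = 1.0,
) -> np.ndarray:
    """Canny edge mask of the smoothed channel.

    ``low``/``high`` are hysteresis thresholds expressed as fractions of the
    maximum gradient magnitude (Sobel, after the detector's internal Gaussian
    of std ``canny_sigma``), so they are invariant to the channel's intensity
    scale.
    """
    if not (0.0 <= low < high <= 1.0):
        raise ValueError("need 0 <= low < high <= 1 for Canny thresholds")
    i_s = np.asarray(i_s, dtype=float)
    sm = ndi.gaussian_filter(i_s, canny_sigma, mode="nearest")
    mag_max = float(np.hypot(ndi.sobel(sm, axis=1), ndi.sobel(sm, axis=0)).max())
    if mag_max == 0.0:
        return np.zeros(i_s.shape, dtype=bool)
    return feature.canny(
        i_s,
        sigma=canny_sigma,
        low_threshold=low * mag_max,
        high_threshold=high * mag_max,
    )


def mask_gradient(d: VectorField, e: np.ndarray) -> VectorField:
    """Restrict the inverse-gradient field to the edge set (zero elsewhere)."""
    e = np.asarray(e, dtype=bool)
    if e.shape != d.shape:
        raise ValueError(f"edge mask shape {e.shape} != field shape {d.shape}")
    return VectorField(np.where(e, d.gx, 0.0), np.where(e, d.gy, 0.0))
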