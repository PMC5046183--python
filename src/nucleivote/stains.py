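"""Stain separation: extract the scalar channel the voting detector operates on.

Histology stains obey the Beer-Lambert law in optical-density (OD) space, where
the OD of each pixel is a nonnegative mixture of per-stain absorption vectors.
Sparse non-negative matrix factorisation (SNMF) of the OD matrix recovers both
the stain vectors and the per-pixel concentration maps without supervision.
The detector itself only needs one scalar raster in which nuclei are darker
than background, so simpler surrogates (raw red channel, Rec.601 luminance)
are also provided and the red channel is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import NMF

__all__ = [
    "StainModel",
    "rgb_to_optical_density",
    "od_to_rgb",
    "snmf_deconvolve",
    "select_channel",
]


@dataclass
class StainModel:
    """Result of an OD-space factorisation.

    Attributes
    ----------
    stain_matrix : (3, n_stains) ndarray
        Column-unit-norm stain OD vectors, ordered by descending blue-channel
        OD (hematoxylin-like stain first).
    concentrations : (n_stains, H, W) ndarray
        Nonnegative per-stain concentration rasters.
    reconstruction_error : float
        Frobenius reconstruction error of the factorisation.
    """

    stain_matrix: np.ndarray
    concentrations: np.ndarray
    reconstruction_error: float


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have at least one pixel")
    return img


def rgb_to_optical_density(img: np.ndarray, background=(255.0, 255.0, 255.0)) -> np.ndarray:
    """Convert an RGB image to per-channel optical density.

    ``od_c = -log10(max(img_c, 1) / background_c)`` for each channel *c*; the
    clamp at 1 avoids the singularity of fully absorbing (zero) pixels.

    Parameters
    ----------
    img : (H, W, 3) array
        8-bit/channel RGB intensities.
    background : length-3 sequence
        Per-channel background (unstained) intensity; must be positive.

    Returns
    -------
    (3, H, W) ndarray of optical densities (>= 0 wherever img <= background).
    """
    img = _validate_rgb(img).astype(float)
    bg = np.asarray(background, dtype=float).reshape(3)
    if np.any(bg <= 0):
        raise ValueError("background intensities must be strictly positive")
    od = -np.log10(np.maximum(img, 1.0) / bg)
    return np.moveaxis(od, 2, 0)


def od_to_rgb(od: np.ndarray, background=(255.0, 255.0, 255.0)) -> np.ndarray:
    """Invert :func:`rgb_to_optical_density` (up to the clamp at intensity 1)."""
    od = np.asarray(od, dtype=float)
    bg = np.asarray(background, dtype=float).reshape(3, 1, 1)
    return np.moveaxis(bg * 10.0 ** (-od), 0, 2)


def snmf_deconvolve(
    od: np.ndarray,
    n_stains: int = 2,
    sparsity_weight: float = 0.1,
    seed: int = 0,
    max_iter: int = 200,
) -> StainModel:
    """Sparse NMF colour deconvolution of an OD raster stack.

    Factorises the 3 x (H*W) OD matrix as ``OD ~ W @ H`` with ``W, H >= 0``,
    an L1 sparsity penalty (weight ``sparsity_weight``) on the concentration
    matrix H, and deterministic NNDSVD-style initialisation. Columns of W are
    normalised to unit Euclidean norm (concentrations rescaled to compensate)
    and ordered by descending blue-channel OD so a hematoxylin-like stain
    comes first.

    Negative OD entries (pixels brighter than background) are clipped to zero
    before factorisation.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[0] != 3:
        raise ValueError(f"expected (3, H, W) OD stack, got shape {od.shape}")
    if n_stains not in (2, 3):
        raise ValueError("n_stains must be 2 or 3")
    h, w = od.shape[1:]
    x = np.clip(od.reshape(3, -1), 0.0, None)
    if not np.any(x > 0):
        raise ValueError("all-zero optical density: nothing to deconvolve")

    model = NMF(
        n_components=n_stains,
        init="nndsvda",
        solver="cd",
        beta_loss="frobenius",
        alpha_W=0.0,
        alpha_H=sparsity_weight,
        l1_ratio=1.0,
        max_iter=max_iter,
        tol=1e-5,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # sklearn's ConvergenceWarning is re-raised with a clearer message
        warnings.simplefilter("ignore")
        stains = model.fit_transform(x)  # (3, n_stains)
    conc = model.components_  # (n_stains, H*W)
    if model.n_iter_ >= max_iter:
        warnings.warn(
            f"SNMF did not converge within {max_iter} iterations; "
            "returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    norms = np.linalg.norm(stains, axis=0)
    norms[norms == 0] = 1.0
    stains = stains / norms
    conc = conc * norms[:, None]
    order = np.argsort(-stains[2])  # blue-channel OD, descending
    stains = stains[:, order]
    conc = conc[order]
    return StainModel(
        stain_matrix=stains,
        concentrations=conc.reshape(n_stains, h, w),
        reconstruction_error=float(model.reconstruction_err_),
    )


def select_channel(
    img: np.ndarray,
    mode: str = "red",
    stain_index: int = 0,
    invert: bool = False,
    n_stains: int = 2,
    sparsity_weight: float = 0.1,
    seed: int = 0,
    background=(255.0, 255.0, 255.0),
) -> np.ndarray:
    """Reduce an RGB image to the single scalar raster used for voting.

    Modes
    -----
    ``red``
        Channel 0 of the image (the documented default; dark nuclei on a
        bright background for hematoxylin-family stains).
    ``luminance``
        Rec.601 weighting 0.299 R + 0.587 G + 0.114 B.
    ``snmf``
        Concentration raster ``stain_index`` of :func:`snmf_deconvolve`,
        rescaled to [0, 255]. Note high concentration (nuclei) is *bright*
        in this mode; combine with ``invert=True`` for the detector's
        dark-nuclei convention.

    ``invert=True`` flips polarity (for channels where nuclei are bright).
    Output has the input's H x W shape with values in [0, 255].
    """
    img = _validate_rgb(img).astype(float)
    if mode == "red":
        out = img[:, :, 0]
    elif mode == "luminance":
        out = 0.299 * img[:, :, 0] + 0.587 * img[:, :, 1] + 0.114 * img[:, :, 2]
    elif mode == "snmf":
        if stain_index >= n_stains:
            raise ValueError(f"stain_index {stain_index} >= n_stains {n_stains}")
        od = rgb_to_optical_density(img, background=background)
        sm = snmf_deconvolve(
            od, n_stains=n_stains, sparsity_weight=sparsity_weight, seed=seed
        )
        c = sm.concentrations[stain_index]
        peak = c.max()
        out = c * (255.0 / peak) if peak > 0 else np.zeros_like(c)
    else:
        raise ValueError(f"unknown channel mode {mode!r}")
    if invert:
        out = 255.0 - out
    return np.clip(out, 0.0, 255.0)
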