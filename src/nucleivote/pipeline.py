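"""End-to-end detection pipeline: RGB tile in, nucleus seed points out.

Stage order: channel selection -> Gaussian smoothing -> Canny edges ->
inverse gradient -> edge masking -> fragment extraction and labelling ->
gradient refinement -> multi-pass voting -> Otsu threshold -> connected
component centroids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from . import gradients, refine as refine_mod, seeds as seeds_mod, stains, voting
from .config import RunConfig

__all__ = ["DetectionResult", "detect", "vote_image"]

log = logging.getLogger("nucleivote")


@dataclass
class DetectionResult:
    seeds: seeds_mod.SeedSet
    vote_image: np.ndarray
    edge_mask: np.ndarray
    fragments: List[refine_mod.EdgeFragment]
    refined: refine_mod.RefinedField
    channel: np.ndarray
    config: RunConfig


def vote_image(img: np.ndarray, cfg: Optional[RunConfig] = None) -> np.ndarray:
    """Convenience wrapper returning only the normalised final vote image."""
    return detect(img, cfg).vote_image


def detect(img: np.ndarray, cfg: Optional[RunConfig] = None) -> DetectionResult:
    """Run the full detection pipeline on an RGB image."""
    cfg = (cfg or RunConfig()).validate()
    channel = stains.select_channel(
        img,
        mode=cfg.channel_mode,
        stain_index=cfg.channel_stain_index,
        invert=cfg.channel_invert,
        sparsity_weight=cfg.snmf_sparsity,
        seed=cfg.snmf_seed,
    )
    i_s = gradients.smooth(channel, cfg.preprocess_sigma_gau)
    edges = gradients.detect_edges(
        i_s, low=cfg.canny_low, high=cfg.canny_high, canny_sigma=cfg.canny_sigma
    )
    fragments = refine_mod.extract_fragments(
        edges, min_size=cfg.refine_min_fragment_size
    )
    if cfg.refine_min_fragment_size > 1:
        # rebuild the edge set from the fragments that survived the size filter
        kept = np.zeros_like(edges)
        for f in fragments:
            kept[f.ys, f.xs] = True
        edges = kept
    d = gradients.inverse_gradient(i_s)
    g = gradients.mask_gradient(d, edges)
    n_valid = n_invalid = 0
    for frag in fragments:
        refine_mod.hull_centroid(frag)
        v = refine_mod.label_pixels(frag, g, theta_max=cfg.refine_theta_max)
        n_valid += int(v.sum())
        n_invalid += int((~v).sum())
    refined = refine_mod.refine(g, fragments, strategy=cfg.refine_strategy)
    params = voting.VotingParams(
        r_min=cfg.vote_r_min,
        r_max=cfg.vote_r_max,
        sigma=cfg.vote_sigma,
        sigma_radial=cfg.vote_sigma_radial,
        delta_max=cfg.vote_delta_max,
        n_passes=cfg.n_passes(),
        schedule=cfg.vote_schedule,
    )
    v_n = voting.run_voting(refined, params)
    t_d = seeds_mod.otsu_threshold(v_n)
    seed_set = seeds_mod.extract_seeds(v_n, t_d, min_area=cfg.seeds_min_area)
    log.info(
        "detect: Q=%d fragments, %d valid / %d invalid edge pixels, "
        "T_D=%.4f, %d seeds",
        len(fragments),
        n_valid,
        n_invalid,
        t_d,
        len(seed_set),
    )
    return DetectionResult(
        seeds=seed_set,
        vote_image=v_n,
        edge_mask=edges,
        fragments=fragments,
        refined=refined,
        channel=channel,
        config=cfg,
    )
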