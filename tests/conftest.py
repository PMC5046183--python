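"""Shared fixtures: phantoms and cached pipeline runs (session-scoped)."""

import numpy as np
import pytest

from nucleivote import phantoms, pipeline
from nucleivote.config import RunConfig

STRATEGIES = ("none", "gs1", "gs2")


@pytest.fixture(scope="session")
def solid_phantom():
    """Clean 10-disk phantom, radii 10-16 px, 5 px boundary gaps."""
    spec = phantoms.random_disk_spec(
        10, height=256, width=256, radius_range=(10.0, 16.0), min_gap=5.0, seed=1
    )
    img, gt = phantoms.make_solid_disks(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def solid_results(solid_phantom):
    """Full-pipeline detection on the solid phantom, one result per strategy."""
    _, img, _ = solid_phantom
    return {
        s: pipeline.detect(img, RunConfig(refine_strategy=s)) for s in STRATEGIES
    }


@pytest.fixture(scope="session")
def annulus_phantom():
    """One hollow nucleus (outer r 15, ring 4) at standard staining contrast."""
    spec = phantoms.PhantomSpec(
        height=96,
        width=96,
        nuclei=[phantoms.Nucleus(center=(48.0, 48.0), radius=15.0, thickness=4.0)],
        noise_sigma=0.0,
        seed=0,
    )
    img, gt = phantoms.make_hollow_nuclei(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def annulus_field(annulus_phantom):
    """Edge-masked inverse-gradient field and labelled fragments of the annulus."""
    from nucleivote import gradients, refine as rf

    _, img, _ = annulus_phantom
    channel = img[:, :, 0].astype(float)
    i_s = gradients.smooth(channel, 1.5)
    edges = gradients.detect_edges(i_s)
    g = gradients.mask_gradient(gradients.inverse_gradient(i_s), edges)
    frags = rf.extract_fragments(edges)
    for f in frags:
        rf.hull_centroid(f)
        rf.label_pixels(f, g)
    return g, frags


@pytest.fixture(scope="session")
def cluster_phantom():
    return phantoms.make_hollow_cluster(seed=0)


@pytest.fixture(scope="session")
def cluster_results(cluster_phantom):
    img, _ = cluster_phantom
    return {
        s: pipeline.detect(img, RunConfig(refine_strategy=s)) for s in STRATEGIES
    }
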