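"""Shared fixtures: rendered synthetic embryos and measured standards.

Session-scoped because renders are the expensive part of the suite; every
test that mutates nothing shares them.
"""

from __future__ import annotations

import numpy as np
import pytest

from wgquant import imgprep, puncta as pc, simulate

OPTICS = "session-1"


@pytest.fixture(scope="session")
def noisy_embryo():
    spec = simulate.EmbryoSpec(seed=1)
    image, truth = simulate.render_embryo(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def noiseless_embryo():
    spec = simulate.EmbryoSpec(seed=1, noise=False)
    image, truth = simulate.render_embryo(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def projections(noisy_embryo):
    """8-µm sum projections of each channel plus foreground and background."""
    spec, image, truth = noisy_embryo
    zs = spec.z_step_um
    proj = {
        role: imgprep.sum_projection(image[idx], 8.0, zs)
        for role, idx in simulate.CHANNEL_ROLES.items()
    }
    proj["foreground"] = imgprep.foreground_mask(image.sum(axis=(0, 1)))
    proj["background"] = imgprep.estimate_background(
        proj["arm"], imgprep.default_background_roi(proj["arm"].shape), proj["foreground"]
    )
    return proj


@pytest.fixture(scope="session")
def measured_standards():
    """Ndc80- and Mif2-like standards measured from two stacks each."""

    def build(name, molecules, seeds):
        stacks = [
            simulate.render_standard(
                simulate.StandardSpec(name=name, molecules_per_structure=molecules, seed=s)
            )[0]
            for s in seeds
        ]
        return pc.measure_standard(
            stacks, molecules, name=name, saturation_level=4095.0, optics_id=OPTICS
        )

    ndc80 = build("ndc80", 306.0, (11, 21))
    mif2 = build("mif2", 58.0, (12, 22))
    return ndc80, mif2


@pytest.fixture(scope="session")
def counted_embryo(noisy_embryo, measured_standards):
    """Detected, integrated, saturation-filtered, dual-standard-counted
    puncta of the noisy wild-type embryo."""
    spec, image, truth = noisy_embryo
    ndc80, mif2 = measured_standards
    gfp = image[simulate.CHANNEL_ROLES["gfp"]]
    dets = pc.measure_puncta(gfp, pc.detect_puncta(gfp), z_step_um=spec.z_step_um, optics_id=OPTICS)
    kept, excluded = pc.saturation_filter([p for p in dets if p.valid], spec.saturation_level)
    counts = [pc.count_molecules(p, ndc80, mif2) for p in kept]
    return spec, truth, kept, excluded, counts


def match_to_truth(centroids, truth, max_dist=2.0):
    """Index of the nearest true punctum for each centroid (xy distance)."""
    from scipy.spatial import cKDTree

    pos = np.array([[p.y, p.x] for p in truth.puncta], dtype=float)
    tree = cKDTree(pos)
    dist, idx = tree.query(np.asarray(centroids, dtype=float))
    return dist, idx
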