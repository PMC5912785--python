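"""High-level reproducible studies combining simulation and quantification.

Each function renders its own synthetic inputs from a seed and runs the full
measurement chain, so a single call reproduces one of the package's headline
numbers: the junctional (membrane) share of Arm recovered by pool
separation, the mean destruction-complex punctum molecule count recovered by
dual-standard calibration, and the single-standard cross-check in which an
Ndc80-brightness spot is counted against the Mif2 standard alone.
"""

from __future__ import annotations

import numpy as np

from . import armquant, imgprep, puncta as pc, simulate
from .roi import Rect

__all__ = [
    "measure_default_standards",
    "membrane_share_study",
    "dual_standard_count_study",
    "single_standard_recovery_study",
]


def interstripe_roi(spec: simulate.EmbryoSpec, w: int = 20, h: int = 160) -> Rect:
    """A Wg-OFF ROI on the interstripe column of the third segment."""
    x_center = spec.x0 + 2 * spec.segment_period_px + int(3.5 * spec.cell_diameter_px)
    return Rect.centered(x_center, (spec.y0 + spec.y1) / 2, w=w, h=h)


def measure_default_standards(
    seed: int, n_stacks: int = 4, optics_id: str = "acq"
) -> tuple[pc.CalibrationStandard, pc.CalibrationStandard]:
    """Render and measure the Ndc80-like (306) and Mif2-like (58) standards.

    Four fields of 60 structures each per standard keep the calibration
    error of the per-molecule intensity near 1%, which the ±15-molecule
    consistency rule needs to stay count-independent.
    """

    def build(name, molecules, offset):
        stacks = [
            simulate.render_standard(
                simulate.StandardSpec(
                    name=name, molecules_per_structure=molecules, seed=seed + offset + k
                )
            )[0]
            for k in range(n_stacks)
        ]
        return pc.measure_standard(
            stacks, molecules, name=name, saturation_level=4095.0, optics_id=optics_id
        )

    return build("ndc80", 306.0, 100), build("mif2", 58.0, 200)


def membrane_share_study(seed: int, noise: bool = False) -> dict:
    """Render a wild-type embryo, build the membrane mask from the junction
    channel, and measure the membrane share of Arm in a Wg-OFF ROI.

    Returns the share as a percentage together with the pool bookkeeping.
    """
    spec = simulate.EmbryoSpec(seed=seed, noise=noise)
    image, truth = simulate.render_embryo(spec)
    zs = spec.z_step_um
    junction = imgprep.sum_projection(image[simulate.CHANNEL_ROLES["junction"]], 8.0, zs)
    arm = imgprep.sum_projection(image[simulate.CHANNEL_ROLES["arm"]], 8.0, zs)
    foreground = imgprep.foreground_mask(image.sum(axis=(0, 1)))
    background = imgprep.estimate_background(
        arm, imgprep.default_background_roi(arm.shape), foreground
    )
    mask = imgprep.segment_membrane(junction)
    roi = interstripe_roi(spec)
    pool = armquant.pool_separation(arm, mask, roi, background=background)
    truth_share = truth.arm_truth_junctional.sum() / (
        truth.arm_truth_junctional.sum() + truth.arm_truth_cytoplasmic.sum()
    )
    return {
        "membrane_share_percent": 100.0 * pool.membrane_share,
        "truth_share_percent": 100.0 * truth_share,
        "pool": pool,
        "roi_area": roi.area,
    }


def dual_standard_count_study(seeds, standard_seed: int = 0) -> dict:
    """Dual-standard molecule counting over wild-type embryos.

    Detects, integrates, saturation-filters and counts every punctum in the
    embryos rendered at ``seeds``; returns the mean accepted count, the
    matching ground-truth mean, and the acceptance rate of the ±15-molecule
    consistency rule.
    """
    ndc80, mif2 = measure_default_standards(standard_seed)
    accepted: list[float] = []
    truth_molecules: list[float] = []
    n_counts = 0
    for seed in seeds:
        spec = simulate.EmbryoSpec(seed=seed)
        image, truth = simulate.render_embryo(spec)
        gfp = image[simulate.CHANNEL_ROLES["gfp"]]
        dets = pc.measure_puncta(
            gfp, pc.detect_puncta(gfp), z_step_um=spec.z_step_um, optics_id=ndc80.optics_id
        )
        kept, _ = pc.saturation_filter([p for p in dets if p.valid], spec.saturation_level)
        counts = [pc.count_molecules(p, ndc80, mif2) for p in kept]
        n_counts += len(counts)
        accepted.extend(c.accepted_count for c in counts if c.accepted)
        truth_molecules.extend(p.molecules for p in truth.puncta)
    return {
        "mean_accepted_count": float(np.mean(accepted)),
        "n_accepted": len(accepted),
        "acceptance_rate": len(accepted) / n_counts,
        "truth_mean": float(np.mean(truth_molecules)),
        "n_puncta_truth": len(truth_molecules),
    }


def single_standard_recovery_study(
    seed: int, reps: int = 20, test_molecules: float = 306.0
) -> dict:
    """Count spots rendered at the Ndc80 default brightness using only the
    Mif2 standard (58 molecules per structure).

    Averages the single-standard estimate over ``reps`` noise realizations;
    an unbiased calibration chain returns ~306 molecules.
    """
    _, mif2 = measure_default_standards(seed)
    estimates: list[float] = []
    for rep in range(reps):
        spec = simulate.StandardSpec(
            name="test",
            molecules_per_structure=test_molecules,
            n_structures=12,
            image_shape=(12, 192, 192),
            seed=seed + 500 + rep,
        )
        stack, _ = simulate.render_standard(spec)
        dets = pc.measure_puncta(stack, pc.detect_puncta(stack), optics_id=mif2.optics_id)
        kept, _ = pc.saturation_filter([p for p in dets if p.valid], spec.saturation_level)
        estimates.extend(p.integrated_intensity / mif2.intensity_per_molecule for p in kept)
    return {
        "mean_estimate": float(np.mean(estimates)),
        "n_spots": len(estimates),
        "reps": reps,
    }
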