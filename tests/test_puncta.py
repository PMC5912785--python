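"""Punctum detection, nested-ROI integration, molecule counting, ranking."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from wgquant import imgprep, puncta as pc, simulate
from tests.conftest import OPTICS, match_to_truth


def synthetic_spot(shape=(9, 41, 41), center=(4, 20, 20), photons=5000.0, background=0.0):
    """A PSF-blurred point source with exactly known photon sum."""
    stack = np.zeros(shape)
    stack[center] = photons
    stack = gaussian_filter(stack, sigma=1.0, mode="constant")
    return stack + background


class TestDetectPuncta:
    def test_blank_stack_gives_empty_list(self):
        assert pc.detect_puncta(np.zeros((6, 40, 40))) == []

    def test_two_well_separated_spots_both_found(self):
        stack = synthetic_spot(shape=(9, 80, 80), center=(4, 30, 25), photons=4000)
        stack += synthetic_spot(shape=(9, 80, 80), center=(4, 30, 55), photons=4000)
        rng = np.random.default_rng(0)
        noisy = rng.poisson(stack + 100).astype(float)
        dets = pc.detect_puncta(noisy)
        assert len(dets) == 2
        xs = sorted(p.centroid[2] for p in dets)
        assert abs(xs[0] - 25) <= 1 and abs(xs[1] - 55) <= 1

    def test_embryo_detection_recall_and_precision(self, noisy_embryo):
        spec, image, truth = noisy_embryo
        dets = pc.detect_puncta(image[simulate.CHANNEL_ROLES["gfp"]])
        dist, _ = match_to_truth([p.centroid[1:] for p in dets], truth)
        precision = (dist <= 2).mean()
        from scipy.spatial import cKDTree

        det_pos = np.array([[p.centroid[1], p.centroid[2]] for p in dets], dtype=float)
        d2, _ = cKDTree(det_pos).query(np.array([[p.y, p.x] for p in truth.puncta], dtype=float))
        recall = (d2 <= 2).mean()
        assert recall >= 0.90
        assert precision >= 0.90

    def test_sorted_by_descending_peak(self, noisy_embryo):
        _, image, _ = noisy_embryo
        dets = pc.detect_puncta(image[3])
        peaks = [p.peak_value for p in dets]
        assert peaks == sorted(peaks, reverse=True)

    def test_z_slices_contiguous(self, noisy_embryo):
        _, image, _ = noisy_embryo
        for p in pc.detect_puncta(image[3]):
            zs = p.z_slices
            assert list(zs) == list(range(zs[0], zs[-1] + 1))
            assert p.centroid[0] in zs


class TestIntegratedIntensity:
    def test_uniform_image_integrates_to_zero(self):
        stack = np.full((7, 50, 50), 42.0)
        p = pc.Punctum(centroid=(3, 25, 25), z_slices=(2, 3, 4))
        assert pc.integrated_intensity(p, stack) == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_photon_sum_on_zero_background(self):
        photons = 5000.0
        stack = synthetic_spot(photons=photons)
        p = pc.Punctum(centroid=(4, 20, 20), z_slices=tuple(range(9)))
        assert pc.integrated_intensity(p, stack) == pytest.approx(photons, rel=0.005)

    def test_invariant_to_constant_background(self):
        stack = synthetic_spot()
        p = pc.Punctum(centroid=(4, 20, 20), z_slices=tuple(range(9)))
        a = pc.integrated_intensity(p, stack)
        b = pc.integrated_intensity(p, stack + 57.0)
        assert a == pytest.approx(b, rel=1e-9)

    def test_edge_clipped_roi_raises(self):
        stack = np.zeros((5, 30, 30))
        p = pc.Punctum(centroid=(2, 5, 15), z_slices=(2,))
        with pytest.raises(ValueError, match="edge"):
            pc.integrated_intensity(p, stack)

    def test_negative_total_clipped_with_warning(self):
        # bright frame, dark center -> negative nested-ROI signal
        stack = np.full((5, 50, 50), 100.0)
        stack[:, 15:36, 15:36] = 100.0
        stack[:, 18:33, 18:33] = 10.0
        p = pc.Punctum(centroid=(2, 25, 25), z_slices=(2,))
        with pytest.warns(UserWarning, match="clipped"):
            assert pc.integrated_intensity(p, stack) == 0.0


class TestMeasureStandard:
    def test_noiseless_per_structure_intensity(self):
        spec = simulate.StandardSpec(
            molecules_per_structure=306, n_structures=12, noise=False, seed=3
        )
        stack, _ = simulate.render_standard(spec)
        std = pc.measure_standard([stack], 306, name="ndc80")
        # symmetric 3-slice capture of the discrete axial PSF
        capture = std.per_structure_intensity / (306 * spec.brightness_per_molecule)
        assert 0.85 <= capture <= 0.92
        assert std.n_structures == 12

    def test_linearity_in_brightness(self):
        out = {}
        for b in (20.0, 40.0):
            spec = simulate.StandardSpec(
                molecules_per_structure=100, n_structures=12, noise=False, seed=3,
                brightness_per_molecule=b,
            )
            stack, _ = simulate.render_standard(spec)
            out[b] = pc.measure_standard([stack], 100).per_structure_intensity
        assert out[40.0] / out[20.0] == pytest.approx(2.0, rel=1e-6)

    def test_standards_intensity_ratio_matches_molecule_ratio(self, measured_standards):
        ndc80, mif2 = measured_standards
        ratio = ndc80.per_structure_intensity / mif2.per_structure_intensity
        assert ratio == pytest.approx(306 / 58, rel=0.05)

    def test_too_few_structures_raises(self):
        spec = simulate.StandardSpec(molecules_per_structure=306, n_structures=4, seed=1)
        stack, _ = simulate.render_standard(spec)
        with pytest.raises(ValueError, match="structures"):
            pc.measure_standard([stack], 306)


class TestCountMolecules:
    def _ideal_standards(self, ipm=35.0):
        a = pc.CalibrationStandard("ndc80", 306, 306 * ipm, 20, 0.0, optics_id="o")
        b = pc.CalibrationStandard("mif2", 58, 58 * ipm, 20, 0.0, optics_id="o")
        return a, b

    def _punctum(self, intensity):
        p = pc.Punctum(centroid=(3, 30, 30), z_slices=(3,))
        p.integrated_intensity = intensity
        p.optics_id = "o"
        p.distance_from_coverslip_um = 3.0
        return p

    def test_calibration_identity_at_mif2_brightness(self):
        a, b = self._ideal_standards()
        count = pc.count_molecules(self._punctum(58 * 35.0), a, b)
        assert count.accepted
        assert count.accepted_count == pytest.approx(58.0)
        assert count.count_by_standard["mif2"] == pytest.approx(58.0)

    def test_linearity_doubling_intensity(self):
        a, b = self._ideal_standards()
        count = pc.count_molecules(self._punctum(2 * 58 * 35.0), a, b)
        assert count.count_by_standard["mif2"] == pytest.approx(116.0)

    def test_rejects_estimates_differing_by_more_than_tolerance(self):
        # estimates 250 vs 270 differ by 20 > 15 -> not accepted
        a = pc.CalibrationStandard("a", 100, 100 * 40.0, 20, 0.0, optics_id="o")
        b = pc.CalibrationStandard("b", 100, 100 * 40.0 * (250 / 270), 20, 0.0, optics_id="o")
        count = pc.count_molecules(self._punctum(250 * 40.0), a, b)
        assert count.count_by_standard["a"] == pytest.approx(250.0)
        assert count.count_by_standard["b"] == pytest.approx(270.0)
        assert not count.accepted
        assert np.isnan(count.accepted_count)

    def test_optics_mismatch_raises(self):
        a, b = self._ideal_standards()
        p = self._punctum(1000.0)
        p.optics_id = "another-session"
        with pytest.raises(ValueError, match="optics"):
            pc.count_molecules(p, a, b)

    def test_saturated_punctum_rejected(self):
        a, b = self._ideal_standards()
        p = self._punctum(1000.0)
        p.saturated = True
        with pytest.raises(ValueError, match="saturated"):
            pc.count_molecules(p, a, b)

    def test_depth_correction_factor(self):
        a, b = self._ideal_standards()
        p = self._punctum(58 * 35.0)
        p.distance_from_coverslip_um = 10.0
        c = pc.count_molecules(p, a, b, attenuation_per_um=0.05)
        assert c.count_by_standard["mif2"] == pytest.approx(58 * np.exp(0.5))


class TestSaturationFilter:
    def _with_max(self, value):
        p = pc.Punctum(centroid=(0, 0, 0))
        p.max_inner_pixel = value
        return p

    def test_no_pixel_at_ceiling_keeps_all(self):
        puncta = [self._with_max(v) for v in (10, 4000, 4094.9)]
        kept, excluded = pc.saturation_filter(puncta, 4095.0)
        assert len(kept) == 3 and not excluded

    def test_infinite_ceiling_is_identity(self):
        puncta = [self._with_max(v) for v in (10, 1e12)]
        kept, excluded = pc.saturation_filter(puncta, float("inf"))
        assert len(kept) == 2 and not excluded

    def test_rendered_overbright_punctum_excluded(self):
        # a spot bright enough to hit the camera ceiling
        spec = simulate.StandardSpec(
            molecules_per_structure=20000, n_structures=3, seed=5, min_separation_px=60
        )
        stack, _ = simulate.render_standard(spec)
        assert stack.max() == spec.saturation_level
        dets = pc.measure_puncta(stack, pc.detect_puncta(stack))
        kept, excluded = pc.saturation_filter(
            [p for p in dets if p.valid], spec.saturation_level
        )
        assert excluded and all(p.saturated for p in excluded)
        assert not kept


class TestClassifyPunctum:
    def test_centroid_on_mask_is_membrane(self):
        mask = np.zeros((40, 40), bool)
        mask[20, :] = True
        p = pc.Punctum(centroid=(2, 20, 15))
        out = pc.classify_punctum(p, mask, np.zeros((40, 40), bool))
        assert out.compartment == "membrane"
        assert out.region == "wg_off"

    def test_empty_mask_means_cytoplasmic(self):
        p = pc.Punctum(centroid=(2, 10, 10))
        out = pc.classify_punctum(p, np.zeros((30, 30), bool), np.ones((30, 30), bool))
        assert out.compartment == "cytoplasmic"
        assert out.region == "wg_on"

    def test_embryo_compartment_and_region_recovery(self, noisy_embryo, counted_embryo):
        spec, image, truth = noisy_embryo
        _, _, kept, _, _ = counted_embryo
        junc = imgprep.sum_projection(image[0], 8.0, spec.z_step_um)
        mask = imgprep.segment_membrane(junc)
        region = truth.wg_region_map()
        puncta = pc.classify_puncta(list(kept), mask, region)
        dist, idx = match_to_truth([p.centroid[1:] for p in puncta], truth)
        agree_comp = agree_reg = total = 0
        for p, d, i in zip(puncta, dist, idx):
            if d > 2:
                continue
            total += 1
            agree_comp += p.compartment == truth.puncta[i].compartment
            agree_reg += (p.region == "wg_on") == (truth.puncta[i].region == "wg_on")
        assert total > 200
        assert agree_comp / total >= 0.90
        assert agree_reg / total >= 0.95


class TestPercentileThresholdRanking:
    def test_fraction_one_covers_entire_foreground(self):
        img = np.random.default_rng(0).random((50, 50))
        fg = img > 0.2
        table, masks = pc.percentile_threshold_ranking(img, fg, fractions=(0.01, 1.0))
        np.testing.assert_array_equal(masks[1.0], fg)

    def test_masks_nested_for_any_image(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(60, 60)) ** 2
        fg = np.ones((60, 60), bool)
        _, masks = pc.percentile_threshold_ranking(
            img, fg, fractions=(0.001, 0.01, 0.2, 0.9)
        )
        fractions = sorted(masks)
        for small, large in zip(fractions, fractions[1:]):
            assert not (masks[small] & ~masks[large]).any()

    def test_non_monotone_fractions_raise(self):
        img = np.ones((10, 10))
        with pytest.raises(ValueError, match="increasing"):
            pc.percentile_threshold_ranking(img, img > 0, fractions=(0.01, 0.01))

    def test_brightness_hierarchy_of_structures(self, noisy_embryo, projections):
        """The brightest pixels sit in Wg-OFF cytoplasmic puncta; membrane
        puncta need a more permissive cutoff; the diffuse Wg-ON cytoplasm
        appears only at the 15% cutoff."""
        spec, image, truth = noisy_embryo
        gfp = projections["gfp"]
        fg = projections["foreground"]
        cls = truth.structure_class_map(punctum_radius=1)
        table, masks = pc.percentile_threshold_ranking(
            gfp, fg, class_map=cls, class_names=simulate.CLASS_NAMES
        )
        cov = table.pivot(index="class", columns="fraction", values="coverage")
        # top 0.1%: overwhelmingly inside Wg-OFF cytoplasmic puncta (their
        # full footprint, radius-2 disks)
        footprint = truth.structure_class_map(punctum_radius=2)
        purity = (footprint[masks[0.001]] == simulate.CLASS_OFF_PUNCTUM).mean()
        assert purity >= 0.90
        # membrane (Wg-ON) puncta only light up by the 1% cutoff
        assert cov.loc["wg_on_punctum", 0.003] < 0.10
        assert cov.loc["wg_on_punctum", 0.01] >= 0.30
        assert cov.loc["wg_off_punctum", 0.01] >= 2 * cov.loc["wg_on_punctum", 0.01]
        # diffuse Wg-ON cytoplasm appears only at the 15% cutoff ...
        assert cov.loc["wg_on_cytoplasm", 0.01] < 0.02
        assert cov.loc["wg_on_cytoplasm", 0.15] >= 0.20
        # ... and far ahead of the Wg-OFF cytoplasm
        assert cov.loc["wg_on_cytoplasm", 0.15] >= 4 * cov.loc["wg_off_cytoplasm", 0.15]


class TestCalibrationProperties:
    def test_cross_standard_agreement_rate(self, counted_embryo):
        # matched optics: >= 95% of unsaturated puncta with true counts
        # <= 400 molecules pass the +/-15 consistency rule
        spec, truth, kept, _, counts = counted_embryo
        dist, idx = match_to_truth([c.punctum.centroid[1:] for c in counts], truth)
        eligible = [
            c for c, d, i in zip(counts, dist, idx)
            if d <= 2 and truth.puncta[i].molecules <= 400
        ]
        assert len(eligible) >= 150
        assert np.mean([c.accepted for c in eligible]) >= 0.95

    def test_calibration_regression_slope_and_intercept(self, measured_standards):
        # isolated spots spanning the 46-931 molecule range, seeds 1-10
        ndc80, mif2 = measured_standards
        est, tru = [], []
        for seed in range(1, 11):
            mols = np.exp(
                np.random.default_rng(1000 + seed).uniform(np.log(46), np.log(931), 25)
            )
            spec = simulate.StandardSpec(name="field", seed=seed, n_structures=25)
            stack, pos = simulate.render_spot_field(spec, mols)
            dets = pc.measure_puncta(stack, pc.detect_puncta(stack), optics_id=OPTICS)
            kept, _ = pc.saturation_filter([p for p in dets if p.valid], 4095.0)
            from scipy.spatial import cKDTree

            tree = cKDTree(np.asarray(pos)[:, 1:])
            for p in kept:
                d, i = tree.query(p.centroid[1:])
                if d <= 2:
                    c = pc.count_molecules(p, ndc80, mif2)
                    if c.accepted:
                        est.append(c.accepted_count)
                        tru.append(mols[i])
        assert len(est) >= 200
        slope, intercept = np.polyfit(tru, est, 1)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert abs(intercept) < 5.0
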