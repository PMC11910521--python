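"""Spot detection, lobe segmentation and compartment quantification."""

import numpy as np
import pytest

from axonloc import spots as sp
from axonloc.simulate import SimulationConfig, simulate_stack
from axonloc.stack import ImageStack
from conftest import greedy_match_count


def gaussian_spot_2d(shape, center, sigma, amplitude):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return amplitude * np.exp(-((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
                              / (2 * sigma ** 2))


class TestRescaleContrast:
    def test_constant_image_unchanged_with_warning(self):
        img = np.full((50, 50), 7.0)
        with pytest.warns(UserWarning, match="constant"):
            out = sp.rescale_contrast(img)
        assert np.array_equal(out, img)

    def test_permutation_saturates_exact_fraction(self):
        rng = np.random.default_rng(0)
        img = rng.permutation(10 ** 6).reshape(1000, 1000).astype(float)
        out = sp.rescale_contrast(img, saturation_fraction=1e-4)
        assert int((out == 1.0).sum()) == 100

    def test_output_minimum_is_zero(self):
        rng = np.random.default_rng(1)
        out = sp.rescale_contrast(rng.normal(50, 10, (64, 64)))
        assert out.min() == 0.0
        assert out.max() == 1.0


class TestDetect2D:
    def test_blank_image_no_spots(self):
        rng = np.random.default_rng(2)
        img = rng.normal(100, 10, (300, 300))
        assert sp.detect_spots_2d(img) == []

    def test_single_planted_spot_found_within_one_pixel(self):
        rng = np.random.default_rng(3)
        sigma_px = (0.4 / 2.355) / 0.07
        img = rng.normal(100, 10, (300, 300)) + gaussian_spot_2d(
            (300, 300), (140, 210), sigma_px, 100.0)  # SNR 10
        found = sp.detect_spots_2d(img)
        assert len(found) == 1
        x_px, y_px = found[0].x / 0.07 - 0.5, found[0].y / 0.07 - 0.5
        assert abs(x_px - 210) <= 1.0 and abs(y_px - 140) <= 1.0

    def test_count_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        img = rng.normal(100, 10, (300, 300))
        sigma_px = (0.4 / 2.355) / 0.07
        for c in [(50, 50), (150, 200), (250, 100), (80, 240)]:
            img += gaussian_spot_2d((300, 300), c, sigma_px, rng.uniform(40, 120))
        counts = [len(sp.detect_spots_2d(img, sp.DetectionParams(response_threshold=t)))
                  for t in (0.2, 0.32, 0.42, 0.62, 0.82, 0.95)]
        assert counts == sorted(counts, reverse=True)

    def test_component_size_cutoff_filters_spots(self):
        rng = np.random.default_rng(5)
        img = rng.normal(100, 5, (200, 200))
        sigma_px = (0.4 / 2.355) / 0.07
        img += gaussian_spot_2d((200, 200), (100, 100), sigma_px, 80.0)
        small_cut = sp.detect_spots_2d(img, sp.DetectionParams(min_component_px=4))
        big_cut = sp.detect_spots_2d(img, sp.DetectionParams(min_component_px=1000))
        assert len(small_cut) == 1
        assert big_cut == []


class TestDetect3D:
    def test_blank_stack_no_spots(self):
        rng = np.random.default_rng(6)
        stack = ImageStack(channels={"spots": rng.normal(100, 10, (20, 80, 80)).clip(0)},
                           voxel_xy=0.07, voxel_z=0.25)
        assert sp.detect_spots_3d(stack, "spots") == []

    def test_too_thin_stack_names_minimum_depth(self):
        stack = ImageStack(channels={"spots": np.ones((2, 40, 40))},
                           voxel_xy=0.07, voxel_z=0.25)
        with pytest.raises(sp.GeometryError, match="z planes"):
            sp.detect_spots_3d(stack, "spots")

    def test_nonoverlapping_spots_high_recall_precision(self):
        cfg = SimulationConfig(seed=2, density_proximal=0.12, density_distal=0.12,
                               spot_amplitude=50.0, noise_sd=10.0,  # SNR 5
                               min_separation=1.0)
        stack, truth = simulate_stack(cfg)
        assert truth.n_spots >= 50
        found = sp.detect_spots_3d(stack, "spots")
        det = np.array([f.position for f in found])
        m = greedy_match_count(truth.spot_positions, det, radius=0.3)
        assert m / truth.n_spots >= 0.95  # recall
        assert m / len(found) >= 0.95  # precision

    def test_two_resolvable_spots_detected_separately(self):
        cfg = SimulationConfig(seed=0, lobe_length=10, lobe_radius=1.5,
                               density_proximal=0, density_distal=0)
        stack, _ = simulate_stack(cfg)
        img = stack.channels["spots"].copy()
        stack2 = ImageStack(channels={"spots": img}, voxel_xy=0.07, voxel_z=0.25)
        from axonloc.simulate import _render_spots

        # 3x the xy diameter apart
        _render_spots(img, [(4.0, 2.0, 2.0), (5.2, 2.0, 2.0)], 300.0,
                      0.4 / 2.355, 0.8 / 2.355, 0.07, 0.25)
        found = sp.detect_spots_3d(stack2, "spots")
        assert len(found) == 2

    def test_count_monotone_in_threshold(self, small_stack):
        _, stack, _ = small_stack
        counts = [len(sp.detect_spots_3d(stack, "spots",
                                         sp.DetectionParams(response_threshold=t)))
                  for t in (0.3, 0.5, 0.62, 0.8, 0.95)]
        assert counts == sorted(counts, reverse=True)

    def test_reported_positions_rebin_to_source_voxel(self, small_stack):
        _, stack, _ = small_stack
        found = sp.detect_spots_3d(stack, "spots")
        vox = stack.voxel_of([f.position for f in found])
        centers = stack.voxel_center(vox)
        assert np.allclose(centers, [f.position for f in found])


class TestSegmentLobe:
    def test_axial_coordinate_monotone_along_cylinder(self, small_stack):
        cfg, stack, truth = small_stack
        region = sp.segment_lobe(stack, "reference")
        zz, yy, xx = np.nonzero(region.mask)
        s = region.s[zz, yy, xx]
        from scipy.stats import spearmanr

        rho, _ = spearmanr(xx, s)
        assert rho > 0.99

    def test_volume_close_to_analytic_cylinder(self, small_stack):
        cfg, stack, _ = small_stack
        region = sp.segment_lobe(stack, "reference")
        expected = np.pi * cfg.lobe_radius ** 2 * cfg.lobe_length
        assert abs(region.volume - expected) / expected < 0.10

    def test_flipping_anchor_reverses_axial_coordinate(self, small_stack):
        cfg, stack, _ = small_stack
        a = sp.segment_lobe(stack, "reference", proximal_anchor=(0, 0, 0))
        far = (cfg.lobe_length + 2 * cfg.margin_xy, 0, 0)
        b = sp.segment_lobe(stack, "reference", proximal_anchor=far)
        m = a.mask
        assert np.allclose(a.s[m], 1.0 - b.s[m], atol=1e-6)

    def test_constant_reference_raises(self):
        stack = ImageStack(channels={"reference": np.ones((10, 20, 20))},
                           voxel_xy=0.07, voxel_z=0.25)
        with pytest.raises(sp.SegmentationError):
            sp.segment_lobe(stack, "reference")


def _truth_spots(truth):
    return [sp.Spot(position=tuple(p), response=1.0) for p in truth.spot_positions]


class TestRegionFiltering:
    def test_planted_spots_are_inside_segmented_region(self, small_stack):
        _, stack, truth = small_stack
        region = sp.segment_lobe(stack, "reference")
        inside = sp.filter_spots_in_region(_truth_spots(truth), region)
        assert len(inside) / truth.n_spots > 0.97

    def test_corner_spot_outside_mask_removed(self, small_stack):
        _, stack, _ = small_stack
        region = sp.segment_lobe(stack, "reference")
        corner = sp.Spot(position=(0.05, 0.05, 0.05), response=1.0)
        assert sp.filter_spots_in_region([corner], region) == []

    def test_inside_outside_partition(self, small_stack):
        _, stack, truth = small_stack
        region = sp.segment_lobe(stack, "reference")
        all_spots = _truth_spots(truth) + [sp.Spot((0.05, 0.05, 0.05), 1.0)]
        inside = sp.filter_spots_in_region(all_spots, region)
        flags = region.contains(all_spots)
        outside = [s for s, f in zip(all_spots, flags) if not f]
        assert len(inside) + len(outside) == len(all_spots)
        assert set(inside).isdisjoint(outside)


class TestAxonalCountAndRatio:
    def test_uniform_spots_retained_at_two_thirds(self, small_stack):
        cfg, stack, _ = small_stack
        region = sp.segment_lobe(stack, "reference")
        rng = np.random.default_rng(12)
        n = 3000
        x = rng.uniform(cfg.margin_xy, cfg.margin_xy + cfg.lobe_length, n)
        r = cfg.lobe_radius * 0.95 * np.sqrt(rng.uniform(0, 1, n))
        th = rng.uniform(0, 2 * np.pi, n)
        cy = stack.shape[1] * cfg.voxel_xy / 2
        cz = stack.shape[0] * cfg.voxel_z / 2
        uniform = [sp.Spot((xi, cy + ri * np.cos(t), cz + ri * np.sin(t)), 1.0)
                   for xi, ri, t in zip(x, r, th)]
        count, _ = sp.count_axonal(uniform, region)
        assert abs(count / n - 2 / 3) <= 0.03

    @pytest.mark.parametrize("n, included", [(9, False), (10, True)])
    def test_exclusion_below_ten_axonal_spots(self, small_stack, n, included):
        cfg, stack, _ = small_stack
        region = sp.segment_lobe(stack, "reference")
        cy = stack.shape[1] * cfg.voxel_xy / 2
        cz = stack.shape[0] * cfg.voxel_z / 2
        distal_x = cfg.margin_xy + 0.9 * cfg.lobe_length
        spots = [sp.Spot((distal_x, cy, cz), 1.0)] * n
        count, flag = sp.count_axonal(spots, region)
        assert count == n and flag is included

    def test_equal_densities_ratio_near_one(self):
        cfg = SimulationConfig(seed=21, lobe_length=30, lobe_radius=2.5,
                               density_proximal=0.5, density_distal=0.5)
        stack, truth = simulate_stack(cfg)
        region = sp.segment_lobe(stack, "reference")
        inside = sp.filter_spots_in_region(_truth_spots(truth), region)
        assert len(inside) >= 200
        q = sp.compartment_ratio(inside, region)
        assert q.enrichment_ratio == pytest.approx(1.0, abs=0.15)

    def test_all_spots_distal_flags_undefined_ratio(self, small_stack):
        cfg, stack, _ = small_stack
        region = sp.segment_lobe(stack, "reference")
        cy = stack.shape[1] * cfg.voxel_xy / 2
        cz = stack.shape[0] * cfg.voxel_z / 2
        spots = [sp.Spot((cfg.margin_xy + 0.95 * cfg.lobe_length, cy, cz), 1.0)] * 20
        q = sp.compartment_ratio(spots, region)
        assert q.enrichment_ratio is None
        assert "proximal" in q.undefined_reason

    def test_partition_conservation(self, small_stack):
        _, stack, truth = small_stack
        region = sp.segment_lobe(stack, "reference")
        inside = sp.filter_spots_in_region(_truth_spots(truth), region)
        q = sp.compartment_ratio(inside, region)
        assert q.n_gamma5 + q.n_gamma24 == len(inside)
        assert q.vol_gamma5 + q.vol_gamma24 == pytest.approx(region.volume)


class TestNormalizeCounts:
    def test_control_mean_is_one_per_batch(self):
        counts = [20, 30, 10, 40, 60, 20]
        groups = ["control", "control", "mutant"] * 2
        batches = [0, 0, 0, 1, 1, 1]
        out = sp.normalize_counts(counts, groups, batches)
        assert out[:2].mean() == pytest.approx(1.0)
        assert out[3:5].mean() == pytest.approx(1.0)

    def test_scale_invariance(self):
        counts = np.array([20.0, 30.0, 10.0])
        groups = ["control", "control", "mutant"]
        a = sp.normalize_counts(counts, groups)
        b = sp.normalize_counts(counts * 2, groups)
        assert np.allclose(a, b)

    def test_known_batch_arithmetic(self):
        out = sp.normalize_counts([20, 30, 10], ["control", "control", "mutant"])
        assert out[2] == pytest.approx(0.4)

    def test_zero_control_mean_errors(self):
        with pytest.raises(ValueError, match="zero"):
            sp.normalize_counts([0, 0, 5], ["control", "control", "mutant"])
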