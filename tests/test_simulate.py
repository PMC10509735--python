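"""Synthetic z-stack generator: geometry, determinism, optics, class signal."""

import dataclasses

import numpy as np
import pytest

from stackmil.errors import ConfigurationError
from stackmil.evaluate import compute_auc
from stackmil.preprocess import sharpness
from stackmil.simulate import (MARKERS, SynthConfig, apply_misalignment,
                               focal_depth, generate_cohort, generate_specimen,
                               generate_tile_scene, make_virtual_stack,
                               render_slice, sigma_defocus)
from stackmil.utils import derive_rng

SMALL = dict(tile_size=32, n_slices=5, nuclei_density=8.0, nucleus_radius_px=3.0,
             nucleus_radius_sd=0.6, tiles_per_specimen_range=(2, 2), seed=1)


class TestConfig:
    @pytest.mark.parametrize("bad", [
        {"n_slices": 0}, {"slice_interval": 0.0}, {"tile_size": 16},
        {"tiles_per_specimen_range": (0, 3)}, {"tiles_per_specimen_range": (5, 2)},
        {"signal_slice_bias": 17}, {"misalignment_px": -1.0},
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            SynthConfig(**bad)

    def test_defaults_match_acquisition_protocol(self):
        cfg = SynthConfig()
        assert (cfg.tile_size, cfg.n_slices, cfg.slice_interval) == (256, 17, 0.5)
        # 17 planes at 0.5 um span 8 um end to end
        span = (cfg.n_slices - 1) * cfg.slice_interval
        assert span == pytest.approx(8.0)


class TestGenerateSpecimen:
    def test_bag_geometry_and_full_scale_stack_shape(self):
        cfg = SynthConfig(tile_size=256, n_slices=17,
                          tiles_per_specimen_range=(5, 5), nuclei_density=12.0,
                          seed=7)
        bag = generate_specimen(cfg, 1, specimen_seed=7)
        assert bag.n_tiles == 5
        for tile in bag.tiles:
            assert tile.pixels.shape == (256, 256, 3, 17)
            assert tile.pixels.dtype == np.uint8

    def test_seeded_determinism_is_byte_identical(self):
        cfg = SynthConfig(**SMALL)
        a = generate_specimen(cfg, 1, specimen_seed=3)
        b = generate_specimen(cfg, 1, specimen_seed=3)
        assert all(np.array_equal(x.pixels, y.pixels)
                   for x, y in zip(a.tiles, b.tiles))
        assert a.labels == b.labels

    def test_morphology_effect_separates_nucleus_area(self):
        """With a strong morphology effect the mean ground-truth nucleus area
        differs between classes by far more than 3 pooled standard errors."""
        cfg = SynthConfig(**{**SMALL, "morphology_effect": 2.0,
                             "tiles_per_specimen_range": (1, 1)})
        areas = {0: [], 1: []}
        for label in (0, 1):
            for s in range(50):
                bag = generate_specimen(cfg, label, specimen_seed=s)
                m = bag.ground_truth_masks[0]
                areas[label].append(m.sum() / bag.tile_meta[0]["n_nuclei"])
        a0, a1 = np.array(areas[0]), np.array(areas[1])
        se = np.sqrt(a0.var(ddof=1) / len(a0) + a1.var(ddof=1) / len(a1))
        assert a1.mean() - a0.mean() > 3 * se

    def test_masks_and_meta_recorded(self):
        bag = generate_specimen(SynthConfig(**SMALL), 0, specimen_seed=1)
        assert len(bag.ground_truth_masks) == bag.n_tiles
        assert all(set(m.flatten()) <= {0, 1} for m in bag.ground_truth_masks)
        assert all(meta["n_nuclei"] >= 1 for meta in bag.tile_meta)

    def test_invalid_label_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_specimen(SynthConfig(**SMALL), 2, specimen_seed=0)


class TestRenderSlice:
    def test_in_focus_slice_is_sharpest(self):
        cfg = SynthConfig(**SMALL)
        scene = generate_tile_scene(cfg, 0, derive_rng(1, "scene"))
        target = 3
        for obj in scene.objects:
            obj.depth_um = focal_depth(target, cfg)
        scene.bg_depth_um = focal_depth(target, cfg)
        scores = [sharpness(render_slice(scene, z, cfg)) for z in range(cfg.n_slices)]
        assert int(np.argmax(scores)) == target
        assert scores[target] > scores[(target + 2) % cfg.n_slices]

    def test_single_plane_stack_renders_in_focus(self):
        cfg1 = SynthConfig(**{**SMALL, "n_slices": 1})
        scene = generate_tile_scene(cfg1, 0, derive_rng(2, "scene"))
        img = render_slice(scene, 0, cfg1)
        # every object treated as in focus: re-rendering at depth 0 matches
        for obj in scene.objects:
            obj.depth_um = focal_depth(0, cfg1)
        scene.bg_depth_um = focal_depth(0, cfg1)
        np.testing.assert_array_equal(img, render_slice(scene, 0, cfg1))

    def test_out_of_range_index_raises(self):
        cfg = SynthConfig(**SMALL)
        scene = generate_tile_scene(cfg, 0, derive_rng(3, "scene"))
        with pytest.raises(IndexError):
            render_slice(scene, cfg.n_slices, cfg)

    def test_defocus_width_nondecreasing_over_stack(self):
        cfg = SynthConfig()  # 17 slices at 0.5 um
        widths = [sigma_defocus(abs(z - 8) * cfg.slice_interval, cfg)
                  for z in range(17)]
        left, right = widths[:9], widths[8:]
        assert all(a >= b for a, b in zip(left, left[1:]))   # decreasing to focus
        assert all(b >= a for a, b in zip(right, right[1:]))  # increasing after
        assert min(widths) == widths[8] == cfg.defocus_sigma0


class TestVirtualStack:
    def test_central_slice_bit_exact_and_sharpness_profile(self):
        # axial_resolution chosen so the per-slice blur increments resolve
        # above uint8 quantization
        cfg = SynthConfig(**{**SMALL, "axial_resolution": 0.5})
        bag = generate_specimen(cfg, 1, specimen_seed=4)
        center = (cfg.n_slices - 1) // 2
        in_focus = bag.tiles[0].pixels[:, :, :, center]
        vt = make_virtual_stack(in_focus, cfg)
        assert vt.pixels.shape == in_focus.shape + (cfg.n_slices,)
        np.testing.assert_array_equal(vt.pixels[:, :, :, center], in_focus)
        scores = [sharpness(vt.pixels[:, :, :, z]) for z in range(cfg.n_slices)]
        assert int(np.argmax(scores)) == center
        assert all(a >= b for a, b in zip(scores[center:], scores[center + 1:]))
        assert all(b >= a for a, b in zip(scores[:center], scores[1:center + 1]))

    def test_degenerate_single_slice(self):
        cfg1 = SynthConfig(**{**SMALL, "n_slices": 1})
        img = np.full((32, 32, 3), 128, dtype=np.uint8)
        vt = make_virtual_stack(img, cfg1)
        assert vt.pixels.shape == (32, 32, 3, 1)
        np.testing.assert_array_equal(vt.pixels[:, :, :, 0], img)

    def test_every_slice_is_function_of_central_only(self):
        """Virtual stacks carry no axial information: rebuilding from the
        central slice alone reproduces the whole stack."""
        cfg = SynthConfig(**SMALL)
        bag = generate_specimen(cfg, 1, specimen_seed=9)
        center = (cfg.n_slices - 1) // 2
        img = bag.tiles[0].pixels[:, :, :, center]
        vt1 = make_virtual_stack(img, cfg)
        vt2 = make_virtual_stack(vt1.pixels[:, :, :, center], cfg)
        np.testing.assert_array_equal(vt1.pixels, vt2.pixels)


class TestMisalignment:
    def test_zero_jitter_is_identity(self):
        cfg = SynthConfig(**SMALL)
        bag = generate_specimen(cfg, 0, specimen_seed=5)
        out, transforms = apply_misalignment(bag, cfg, seed=1)
        assert all(np.array_equal(a.pixels, b.pixels)
                   for a, b in zip(bag.tiles, out.tiles))
        assert all(t == {"tx": 0.0, "ty": 0.0, "deg": 0.0}
                   for per_tile in transforms for t in per_tile)

    def test_jitter_bounded_and_deterministic(self):
        cfg = SynthConfig(**{**SMALL, "misalignment_px": 3.0,
                             "misalignment_deg": 2.0})
        bag = generate_specimen(cfg, 0, specimen_seed=5)
        out1, tf1 = apply_misalignment(bag, cfg, seed=2)
        out2, tf2 = apply_misalignment(bag, cfg, seed=2)
        assert tf1 == tf2
        assert all(np.array_equal(a.pixels, b.pixels)
                   for a, b in zip(out1.tiles, out2.tiles))
        ref = (cfg.n_slices - 1) // 2
        for per_tile in tf1:
            for z, t in enumerate(per_tile):
                assert max(abs(t["tx"]), abs(t["ty"])) <= 3.0
                assert abs(t["deg"]) <= 2.0
                if z == ref:
                    assert t == {"tx": 0.0, "ty": 0.0, "deg": 0.0}


class TestCohort:
    @pytest.mark.parametrize("n,frac,expected_pos", [
        (20, 0.5, 10),
        (401, 0.781, 313),   # printed positive ratio of the ER marker
    ])
    def test_positive_counts(self, n, frac, expected_pos):
        cfg = SynthConfig(**{**SMALL, "tiles_per_specimen_range": (1, 1),
                             "nuclei_density": 2.0})
        if n > 50:  # the count rule alone; rendering 401 bags is pointless here
            assert int(round(n * frac)) == expected_pos
            return
        bags, table = generate_cohort(cfg, n, frac, seed=3)
        assert int(table[MARKERS[0]].sum()) == expected_pos
        assert len(bags) == n

    def test_label_table_deterministic(self):
        cfg = SynthConfig(**{**SMALL, "tiles_per_specimen_range": (1, 1)})
        _, t1 = generate_cohort(cfg, 8, 0.5, seed=9)
        _, t2 = generate_cohort(cfg, 8, 0.5, seed=9)
        assert t1.equals(t2)

    @pytest.mark.parametrize("n,frac", [(1, 0.5), (10, 0.0), (10, 1.0)])
    def test_degenerate_cohorts_rejected(self, n, frac):
        with pytest.raises(ConfigurationError):
            generate_cohort(SynthConfig(**SMALL), n, frac, seed=0)


class TestAxialInformation:
    def test_biased_slice_carries_the_class_signal(self):
        """With signal_slice_bias set, a threshold statistic on the biased
        slice separates classes while the same statistic on a distal slice
        stays near chance."""
        cfg = SynthConfig(tile_size=32, n_slices=9, slice_interval=1.5,
                          nuclei_density=14.0, nucleus_radius_px=3.0,
                          nucleus_radius_sd=0.6, signal_slice_bias=0,
                          tiles_per_specimen_range=(3, 3), distractor_rate=0.3,
                          seed=2)
        bags, _ = generate_cohort(cfg, 40, 0.5, seed=4)
        y = [b.labels["ER"] for b in bags]

        def grad_energy(img):
            g = img.astype(float).mean(axis=2)
            return np.abs(np.diff(g, axis=1)).mean()

        def bag_stat(bag, z):
            return float(np.mean([grad_energy(t.pixels[:, :, :, z])
                                  for t in bag.tiles]))

        auc_biased = compute_auc(y, [bag_stat(b, 0) for b in bags])
        auc_distal = compute_auc(y, [bag_stat(b, 8) for b in bags])
        auc_biased = max(auc_biased, 1 - auc_biased)
        auc_distal = max(auc_distal, 1 - auc_distal)
        assert auc_biased > 0.85
        assert auc_biased > auc_distal + 0.15
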