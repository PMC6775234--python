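"""Mask builders: rasterization, fibrosis accounting, ring geometry, scars."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from fibrovw import geometry as geo
from fibrovw.geometry import Label


class TestSquareInfarct:
    def test_equal_width_annuli_have_odd_area_ratios(self):
        _, layers = geo.build_square_with_circular_infarct(
            1000, 0.25, [70, 140, 210, 280, 350])
        areas = np.array([len(l) for l in layers], dtype=float)
        np.testing.assert_allclose(areas / areas[0], [1, 3, 5, 7, 9], rtol=0.02)

    def test_single_disk_node_count_matches_area(self):
        g, layers = geo.build_square_with_circular_infarct(100, 0.25, [10])
        assert len(layers) == 1
        assert len(layers[0]) == pytest.approx(math.pi * 100, rel=0.05)
        assert g.count(Label.INFARCT) == len(layers[0])

    def test_layers_partition_the_infarct_exactly(self):
        g, layers = geo.build_square_with_circular_infarct(200, 0.25, [14, 28, 42, 56, 70])
        allidx = np.concatenate(layers)
        assert len(np.unique(allidx)) == allidx.size
        assert np.array_equal(np.sort(allidx), g.indices_of(Label.INFARCT))

    def test_circle_exceeding_grid_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            geo.build_square_with_circular_infarct(100, 0.25, [350])


class TestFibrosis:
    def test_exact_counts_and_region_restriction(self):
        g, layers = geo.build_square_with_circular_infarct(200, 0.25, [70])
        region = layers[0]
        out = geo.sprinkle_random_fibrosis(g, region, 23.0, seed=1)
        want = int(math.floor(0.23 * region.size + 0.5))
        assert out.count(Label.FIBROTIC) == want
        # fibrosis stays inside the region
        outside = np.setdiff1d(np.arange(g.labels.size), region)
        assert not np.any(out.labels.ravel()[outside] == Label.FIBROTIC)

    def test_zero_percent_is_identity(self):
        g, layers = geo.build_square_with_circular_infarct(100, 0.25, [30])
        out = geo.sprinkle_random_fibrosis(g, layers[0], 0.0, seed=3)
        assert np.array_equal(out.labels, g.labels)

    def test_seed_determinism_and_seed_sensitivity(self):
        g, layers = geo.build_square_with_circular_infarct(100, 0.25, [30])
        a = geo.sprinkle_random_fibrosis(g, layers[0], 20, seed=5)
        b = geo.sprinkle_random_fibrosis(g, layers[0], 20, seed=5)
        c = geo.sprinkle_random_fibrosis(g, layers[0], 20, seed=6)
        assert np.array_equal(a.labels, b.labels)
        assert not np.array_equal(a.labels, c.labels)
        assert a.count(Label.FIBROTIC) == c.count(Label.FIBROTIC)

    def test_void_region_rejected(self):
        spec = geo.RingSpec(grid_n=80)
        g, _ = geo.build_ring(spec, 0.35)
        with pytest.raises(ValueError, match="VOID"):
            geo.sprinkle_random_fibrosis(g, np.arange(10), 10, seed=0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(percent=st.floats(0, 100), size=st.integers(1, 4000), seed=st.integers(0, 99))
    def test_realized_count_is_rounded_share_of_region(self, percent, size, seed):
        g = geo.TissueGrid(np.full((64, 64), Label.NORMAL, dtype=np.int8), 0.25)
        region = np.arange(size)
        out = geo.sprinkle_random_fibrosis(g, region, percent, seed)
        assert out.count(Label.FIBROTIC) == int(math.floor(percent / 100 * size + 0.5))


class TestGradient:
    def test_default_profile_mean_is_21_percent(self):
        assert geo.GradientSpec(geo.DEFAULT_GRADIENT_PROFILE).mean_percent == pytest.approx(21.0)

    def test_match_to_mean_is_fixed_point_at_21(self):
        spec = geo.match_gradient_to_mean(21.0)
        assert spec.percents == pytest.approx(geo.DEFAULT_GRADIENT_PROFILE)

    @pytest.mark.parametrize("target", [6.0, 42.0])
    def test_match_to_mean_preserves_ratios(self, target):
        spec = geo.match_gradient_to_mean(target)
        expect = tuple(p * target / 21.0 for p in geo.DEFAULT_GRADIENT_PROFILE)
        assert spec.percents == pytest.approx(expect)
        assert spec.mean_percent == pytest.approx(target)
        assert max(spec.percents) <= 100.0

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            geo.match_gradient_to_mean(63.0)   # innermost layer would need 105%

    def test_per_layer_counts_within_one_node(self):
        g, layers = geo.build_square_with_circular_infarct(
            200, 0.25, [18, 36, 54, 72])
        spec = geo.GradientSpec(geo.SCAR_GRADIENT_PROFILE,
                                weights=[len(l) for l in layers])
        out = geo.apply_gradient_fibrosis(g, layers, spec, seed=2)
        flat = out.labels.ravel()
        for lay, pct in zip(layers, spec.percents):
            got = int(np.count_nonzero(flat[lay] == Label.FIBROTIC))
            assert abs(got - pct / 100 * lay.size) <= 1


class TestRing:
    def test_full_length_transmural_infarct_covers_wall(self):
        spec = geo.RingSpec(grid_n=100, length_frac=1.0, width_frac=1.0,
                            distance_frac=0.0)
        g, inf = geo.build_ring(spec, 0.35)
        assert g.count(Label.NORMAL) == 0
        assert g.count(Label.INFARCT) == inf.size > 0

    def test_zero_length_gives_no_infarct(self):
        spec = geo.RingSpec(grid_n=100, length_frac=0.0)
        g, inf = geo.build_ring(spec, 0.35)
        assert inf.size == 0 and g.count(Label.INFARCT) == 0

    def test_sector_node_count_matches_analytic_area(self):
        spec = geo.RingSpec(grid_n=240, length_frac=0.25, width_frac=0.5,
                            distance_frac=0.0)
        g, inf = geo.build_ring(spec, 0.35)
        r_in, r_out = spec.resolve(0.35)
        w = r_out - r_in
        area = 0.25 * math.pi * ((r_in + 0.5 * w) ** 2 - r_in ** 2)  # mm^2
        assert inf.size * 0.35 ** 2 == pytest.approx(area, rel=0.03)

    def test_mask_mirror_symmetric_about_infarct_bisector(self):
        spec = geo.RingSpec(grid_n=120, length_frac=0.3, width_frac=0.6,
                            distance_frac=0.2)
        g, _ = geo.build_ring(spec, 0.35)
        assert np.array_equal(g.labels, g.labels[::-1, :])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="width_frac"):
            geo.RingSpec(grid_n=100, width_frac=0.7, distance_frac=0.7).validate(0.35)
        with pytest.raises(ValueError, match="degenerate"):
            geo.RingSpec(grid_n=100, outer_radius_mm=5.0,
                         inner_radius_mm=6.0).validate(0.35)


class TestSyntheticScar:
    def test_scar_is_single_component_inside_wall(self):
        g, scar, layers = geo.generate_synthetic_scar(seed=7)
        lab, n = ndimage.label(g.labels == Label.INFARCT)
        assert n == 1
        assert sum(len(l) for l in layers) == scar.size
        assert len(np.unique(np.concatenate(layers))) == scar.size

    def test_different_seeds_give_different_partitionable_scars(self):
        g1, s1, l1 = geo.generate_synthetic_scar(seed=1)
        g2, s2, l2 = geo.generate_synthetic_scar(seed=2)
        assert not np.array_equal(g1.labels, g2.labels)
        assert len(l1) == len(l2) == 4

    def test_scar_area_fraction_within_bounds(self):
        bounds = (0.05, 0.35)
        g, scar, _ = geo.generate_synthetic_scar(seed=3, scar_frac_bounds=bounds)
        wall = g.count(Label.NORMAL) + g.count(Label.INFARCT)
        frac = scar.size / wall
        assert bounds[0] * 0.5 <= frac <= bounds[1] * 1.5

    def test_generator_is_deterministic_per_seed(self):
        g1, *_ = geo.generate_synthetic_scar(seed=11)
        g2, *_ = geo.generate_synthetic_scar(seed=11)
        assert np.array_equal(g1.labels, g2.labels)


class TestTransmuralSubtypes:
    def test_band_widths_follow_25_35_40_along_rays(self):
        spec = geo.RingSpec(grid_n=200, length_frac=0.0)
        g, _ = geo.build_ring(spec, 0.35)
        sub = geo.assign_transmural_subtypes(g, (25, 35, 40))
        # walk the horizontal ray rightward from the center
        row = (g.shape[0] - 1) // 2
        right = sub[row, g.shape[1] // 2:]
        right = right[right >= 0]
        widths = np.array([np.count_nonzero(right == k) for k in range(3)], float)
        np.testing.assert_allclose(widths / widths.sum(), [0.25, 0.35, 0.40],
                                   atol=1.5 / widths.sum())
        # monotone inner -> outer
        assert np.all(np.diff(right) >= 0)

    def test_degenerate_ratio_assigns_everything_to_m(self):
        spec = geo.RingSpec(grid_n=100, length_frac=0.0)
        g, _ = geo.build_ring(spec, 0.35)
        sub = geo.assign_transmural_subtypes(g, (0, 100, 0))
        wall = sub[sub >= 0]
        assert np.all(wall == 1)

    def test_open_geometry_rejected(self):
        g = geo.TissueGrid(np.full((64, 64), Label.NORMAL, dtype=np.int8), 0.25)
        with pytest.raises(ValueError, match="open geometry"):
            geo.assign_transmural_subtypes(g)


class TestImageRoundTrip:
    def test_png_roundtrip_preserves_labels(self, tmp_path):
        g, scar, _ = geo.generate_synthetic_scar(seed=5)
        path = tmp_path / "mask.png"
        g.to_image(path)
        back = geo.TissueGrid.from_image(path, g.dx)
        assert np.array_equal(back.labels, g.labels)
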