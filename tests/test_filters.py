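"""Kernels and feature images: constructions, oracles, [0, 1] contracts."""

import math

import numpy as np
import pytest

from cawall import filters
from cawall.ddp import DdpConfig

from oracles import brute_force_correlate

THETAS = filters.DEFAULT_ORIENTATIONS


class TestMacleod:
    @pytest.mark.parametrize("theta", THETAS)
    def test_weights_sum_to_zero(self, theta):
        k = filters.build_macleod(7, 2.0, 2.0, theta)
        assert abs(k.weights.sum()) < 1e-10

    @pytest.mark.parametrize("theta", THETAS)
    def test_constant_image_gives_zero_response(self, theta):
        k = filters.build_macleod(7, 2.0, 2.0, theta)
        resp = filters.kernel_response(np.full((15, 15), 0.5), k)
        np.testing.assert_allclose(resp, 0.0, atol=1e-12)

    def test_horizontal_orientation_antisymmetric_across_edge_axis(self):
        # theta=0: d_xy = -y, so weight(x, y) = -weight(x, -y)
        w = filters.build_macleod(7, 2.0, 2.0, 0.0).weights
        np.testing.assert_allclose(w, -np.flipud(w), atol=1e-14)

    def test_vertical_orientation_antisymmetric_in_x(self):
        w = filters.build_macleod(7, 2.0, 2.0, math.pi / 2).weights
        np.testing.assert_allclose(w, -np.fliplr(w), atol=1e-14)

    def test_even_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            filters.build_macleod(6, 2.0, 2.0, 0.0)


class TestImtKernels:
    def test_three_plus_three_minus_entries_summing_to_zero(self):
        for wall in ("near", "far"):
            w = filters.build_imt_kernel(wall).weights
            assert w.shape == (7, 7)
            assert (w == 1).sum() == 3
            assert (w == -1).sum() == 3
            assert w.sum() == 0

    def test_near_is_point_reflection_of_far(self):
        far = filters.build_imt_kernel("far").weights
        near = filters.build_imt_kernel("near").weights
        assert np.array_equal(np.rot90(far, 2), near)

    def test_constant_image_zero_response(self):
        resp = filters.kernel_response(
            np.full((12, 12), 0.3), filters.build_imt_kernel("far")
        )
        np.testing.assert_allclose(resp, 0.0, atol=1e-12)

    def test_ld_kernels_are_vertical_mirrors(self):
        far = filters.build_ld_kernel("far").weights
        near = filters.build_ld_kernel("near").weights
        assert np.array_equal(np.flipud(far), near)
        assert far.sum() == 0

    def test_outer_kernel_column_vector(self):
        w = filters.build_outer_kernel().weights
        assert w.shape == (9, 1)
        assert np.array_equal(w.ravel(), [-1, -1, -1, -1, 0, 1, 1, 1, 1])

    def test_kernel_text_export_roundtrips(self):
        k = filters.build_imt_kernel("far")
        text = k.to_text()
        body = [line.split() for line in text.splitlines()[1:]]
        np.testing.assert_allclose(np.array(body, dtype=float), k.weights)


class TestFeatureF:
    def test_constant_roi_gives_all_zero(self):
        fmap = filters.compute_feature_F(np.full((10, 10), 0.4),
                                         filters.build_imt_kernel("far"))
        np.testing.assert_allclose(fmap.values, 0.0)

    def test_raw_feature_matches_brute_force_convolution(self, rng):
        image = rng.random((12, 12))
        fx = filters.build_imt_kernel("far")
        raw = sum(
            np.abs(brute_force_correlate(image, filters.build_macleod(7, 2.0, 2.0, th).weights))
            for th in THETAS
        ) + brute_force_correlate(image, fx.weights)
        expected = (raw - raw.min()) / (raw.max() - raw.min())
        fmap = filters.compute_feature_F(image, fx)
        np.testing.assert_allclose(fmap.values, expected, atol=1e-10)

    def test_zero_fx_equals_pure_macleod_magnitude(self, rng):
        image = rng.random((12, 12))
        with_zeros = filters.compute_feature_F(image, np.zeros((7, 7)))
        without = filters.compute_feature_F(image, None)
        np.testing.assert_allclose(with_zeros.values, without.values)

    def test_values_bounded(self, rng):
        fmap = filters.compute_feature_F(rng.random((16, 16)),
                                         filters.build_imt_kernel("near"))
        assert fmap.values.min() >= 0.0
        assert fmap.values.max() <= 1.0

    def test_kernel_larger_than_roi_rejected(self):
        with pytest.raises(ValueError, match="larger than ROI"):
            filters.compute_feature_F(np.zeros((5, 5)), filters.build_imt_kernel("far"))

    def test_unnormalized_image_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            filters.compute_feature_F(np.full((10, 10), 2.0),
                                      filters.build_imt_kernel("far"))

    def test_argmax_rows_track_far_wall_on_noise_free_phantom(self, static_phantom):
        from cawall.phantom import default_roi

        cfg, seq, truth = static_phantom
        roi = default_roi(truth, "imt_far")
        sub = roi.extract(seq.frames[0])
        sub = (sub - sub.min()) / (sub.max() - sub.min())
        fmap = filters.compute_feature_F(sub, filters.build_imt_kernel("far"))
        argmax = fmap.values.argmax(axis=0) + roi.y0
        ti = truth.far_intima[0, roi.columns]
        ta = truth.far_adventitia[0, roi.columns]
        near_either = np.minimum(np.abs(argmax - ti), np.abs(argmax - ta))
        assert near_either.max() <= 1.0


class TestFeatureH:
    def test_all_dark_gives_one_inside_band(self):
        h = filters.compute_feature_H(np.zeros((20, 6)), y_outer=2, r=5)
        band = h.values[3 : 20 - 5]
        np.testing.assert_allclose(band, 1.0)

    def test_all_bright_gives_zero_inside_band(self):
        h = filters.compute_feature_H(np.ones((20, 6)), y_outer=2, r=5)
        band = h.values[3 : 20 - 5]
        np.testing.assert_allclose(band, 0.0)

    def test_windowed_mean_hand_case(self):
        # bright exactly in the r rows below row q -> H(q) = 0; far above -> 1
        m, r, q = 30, 4, 15
        image = np.zeros((m, 3))
        image[q + 1 : q + 1 + r, :] = 1.0
        h = filters.compute_feature_H(image, y_outer=1, r=r).values
        assert h[q, 0] == pytest.approx(0.0)
        assert h[5, 0] == pytest.approx(1.0)

    def test_band_contract_outside_rows_are_one(self, rng):
        m, n, r = 25, 8, 5
        y_outer = rng.integers(2, 8, size=n)
        h = filters.compute_feature_H(rng.random((m, n)), y_outer, r=r).values
        rows = np.arange(m)[:, None]
        outside = ~((rows > y_outer[None, :]) & (rows < m - r))
        np.testing.assert_allclose(h[outside], 1.0)

    def test_r_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="r must"):
            filters.compute_feature_H(np.zeros((10, 4)), 0, r=10)


class TestCombineNearWall:
    def test_c_zero_is_normalized_one_minus_f(self, rng):
        f = filters.FeatureMap(rng.random((10, 10)), "F")
        h = filters.FeatureMap(rng.random((10, 10)), "H")
        out = filters.combine_near_wall(f, h, c=0.0)
        np.testing.assert_allclose(out.values, filters.normalize_map(1.0 - f.values))

    def test_degenerate_combination_returns_half(self):
        f = filters.FeatureMap(np.zeros((6, 6)), "F")
        h = filters.FeatureMap(np.ones((6, 6)), "H")
        out = filters.combine_near_wall(f, h, c=0.5)
        np.testing.assert_allclose(out.values, 0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            filters.combine_near_wall(np.zeros((5, 5)), np.zeros((5, 6)))

    def test_h_term_sharpens_boundary_minima_under_subintima_noise(self):
        """Column-wise minima of 1-F+cH land on the true interfaces more
        often than those of 1-F alone when a bright sub-intima layer is
        present (the dual-line ambiguity scenario)."""
        from cawall import (
            PhantomConfig,
            SubintimaNoiseSpec,
            default_roi,
            generate_sequence,
        )
        from cawall.ddp import DdpConfig, run_single_dp

        cfg = PhantomConfig(
            n_frames=2, seed=19,
            subintima_noise=SubintimaNoiseSpec(frames=((0, 2),), smooth_cols=25.0),
        )
        seq, truth = generate_sequence(cfg)
        roi = default_roi(truth, "imt_near")
        sub = roi.extract(seq.frames[0])
        sub = (sub - sub.min()) / (sub.max() - sub.min())
        fx = filters.build_imt_kernel("far").weights
        fmap = filters.compute_feature_F(sub, -fx)
        f1 = filters.FeatureMap(
            filters.normalize_map(filters.kernel_response(sub, filters.build_outer_kernel())),
            "outer",
        )
        y_outer = run_single_dp(f1, DdpConfig(orientation="maximize_feature"))
        hmap = filters.compute_feature_H(sub, y_outer, r=5)

        ti = truth.near_intima[0, roi.columns] - roi.y0
        ta = truth.near_adventitia[0, roi.columns] - roi.y0

        def hit_count(cost):
            hits = 0
            for x in range(cost.shape[1]):
                col = cost[:, x]
                interior = (col[1:-1] <= col[:-2]) & (col[1:-1] <= col[2:])
                minima = np.where(interior)[0] + 1
                if minima.size < 2:
                    continue
                two = minima[np.argsort(col[minima])[:2]]
                lo, hi = sorted(two)
                if abs(lo - ta[x]) <= 1.0 and abs(hi - ti[x]) <= 1.0:
                    hits += 1
            return hits

        plain = hit_count(1.0 - fmap.values)
        combined = hit_count(filters.combine_near_wall(fmap, hmap, c=0.5).values)
        assert combined > plain
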