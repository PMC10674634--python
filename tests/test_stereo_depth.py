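import itertools

import numpy as np
import pytest

from kelpyield.camera_geometry import CameraModel
from kelpyield.stereo_depth import (
    DisparityMap,
    SgmParams,
    aggregate_paths,
    compute_disparity,
    load_disparity,
    matching_cost,
    median_scene_distance,
    save_disparity,
    select_disparity,
)

from _reference_sgm import ref_aggregate, ref_compute_disparity, ref_matching_cost


def textured(rng, shape):
    """Band-limited, non-saturating random texture (no flat ambiguity)."""
    from scipy.ndimage import gaussian_filter

    tex = gaussian_filter(rng.normal(size=shape), 1.2)
    tex = (tex - tex.mean()) / tex.std()
    return np.clip(128 + 45 * tex, 0, 255).astype(np.uint8)


def tiny_params(**kw):
    defaults = dict(block_size=3, disparity_range=(0, 4), n_paths=8)
    defaults.update(kw)
    return SgmParams(**defaults)


class TestMatchingCost:
    def test_identical_images_zero_cost_at_d0(self, rng):
        img = rng.integers(0, 255, (10, 12)).astype(np.uint8)
        cost = matching_cost(img, img, tiny_params())
        assert np.all(cost[:, :, 0] == 0)

    def test_shifted_pair_minimized_at_true_shift(self, rng):
        left = rng.integers(0, 255, (12, 24)).astype(np.uint8)
        right = np.zeros_like(left)
        right[:, :-4] = left[:, 4:]
        cost = matching_cost(left, right, tiny_params(disparity_range=(0, 7)))
        interior = cost[2:-2, 8:-6, :]
        assert np.all(interior.argmin(axis=-1) == 4)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            matching_cost(np.zeros((4, 4)), np.zeros((4, 5)), tiny_params())

    def test_equals_brute_force_reference(self, rng):
        left = rng.integers(0, 255, (8, 8)).astype(np.uint8)
        right = rng.integers(0, 255, (8, 8)).astype(np.uint8)
        p = tiny_params()
        assert np.array_equal(matching_cost(left, right, p),
                              ref_matching_cost(left, right, p))


class TestAggregatePaths:
    def test_vanishing_penalties_reduce_to_n_paths_times_cost(self, rng):
        cost = rng.uniform(0, 100, (6, 7, 4))
        p = tiny_params(penalty_small=1e-9, penalty_large=2e-9)
        assert np.allclose(aggregate_paths(cost, p), 8 * cost, atol=1e-5)

    def test_single_row_matches_exhaustive_viterbi(self, rng):
        """1-path aggregation on a 6-pixel row equals exhaustive enumeration
        over all 4^6 disparity sequences, up to the per-column normalizer."""
        nd, n = 4, 6
        cost = np.round(rng.uniform(0, 50, (1, n, nd)))
        p = tiny_params(n_paths=1, penalty_small=7, penalty_large=23)

        def pen(a, b):
            return 0 if a == b else (p.p1 if abs(a - b) == 1 else p.p2)

        # V[x, d]: minimal cost over all disparity sequences ending at (x, d)
        V = np.full((n, nd), np.inf)
        for seq in itertools.product(range(nd), repeat=n):
            c = 0.0
            for x, d in enumerate(seq):
                c += cost[0, x, d] + (pen(seq[x - 1], d) if x else 0)
                V[x, d] = min(V[x, d], c)
        L = aggregate_paths(cost, p)[0]
        for x in range(n):
            assert np.allclose(L[x] - L[x].min(), V[x] - V[x].min())

    def test_nonnegative_and_finite(self, rng):
        cost = rng.uniform(0, 1000, (5, 9, 6))
        agg = aggregate_paths(cost, tiny_params(disparity_range=(0, 5)))
        assert np.all(np.isfinite(agg)) and np.all(agg >= 0)

    def test_equals_loop_reference_all_direction_sets(self, rng):
        cost = np.round(rng.uniform(0, 200, (7, 6, 5)))
        for n_paths in (1, 2, 4, 8):
            p = tiny_params(n_paths=n_paths, disparity_range=(0, 4))
            assert np.array_equal(aggregate_paths(cost, p),
                                  ref_aggregate(cost, p))


class TestSelectDisparity:
    def test_unique_minima_argmin(self):
        vol = np.full((2, 2, 5), 100.0)
        vol[0, 0, 3] = 1.0
        vol[1, 1, 0] = 2.0
        p = tiny_params(subpixel=False, uniqueness_ratio=0.0)
        disp = select_disparity(vol, p)
        assert disp.values[0, 0] == 3 and disp.values[1, 1] == 0

    def test_argmin_tie_breaks_to_lowest_disparity(self):
        vol = np.full((1, 1, 5), 10.0)
        p = tiny_params(subpixel=False, uniqueness_ratio=0.0)
        assert select_disparity(vol, p).values[0, 0] == 0

    @pytest.mark.parametrize(
        "costs,method,offset",
        [
            ((4.0, 2.0, 4.0), "parabola", 0.0),
            ((4.0, 2.0, 3.0), "parabola", 1.0 / 6.0),
            ((4.0, 2.0, 3.0), "equiangular", 0.25),
        ],
    )
    def test_subpixel_three_point_fits(self, costs, method, offset):
        vol = np.full((1, 1, 5), 50.0)
        vol[0, 0, 1:4] = costs
        p = tiny_params(uniqueness_ratio=0.0, subpixel_method=method)
        assert select_disparity(vol, p).values[0, 0] == pytest.approx(2 + offset)

    def test_uniqueness_flags_flat_costs_invalid(self):
        vol = np.full((3, 3, 6), 40.0)
        p = tiny_params(disparity_range=(0, 5))
        assert not select_disparity(vol, p).valid.any()


class TestComputeDisparity:
    def test_uniform_shift_recovered(self, rng):
        base = textured(rng, (32, 44))
        left = base[:, :-4]  # d = x_left - x_right = +4
        right = base[:, 4:]
        p = SgmParams(block_size=5, disparity_range=(0, 7))
        disp = compute_disparity(left, right, p)
        interior = np.s_[4:-4, 10:-4]
        vals = disp.values[interior][disp.valid[interior]]
        assert vals.size > 0.5 * disp.values[interior].size
        assert np.all(np.abs(vals - 4) <= 0.25)

    def test_textureless_pair_mostly_invalid(self):
        flat = np.full((24, 24), 120, dtype=np.uint8)
        disp = compute_disparity(flat, flat, tiny_params(disparity_range=(0, 6)))
        assert disp.valid.mean() < 0.5

    def test_synthetic_sheet_median_disparity(self, sheet_render, fast_sgm):
        """Sheet at 2.5 m, f=500, b=0.095: median valid disparity 19 +/- 0.5."""
        disp = compute_disparity(
            sheet_render.left_gray, sheet_render.right_gray, fast_sgm
        )
        med = np.median(disp.values[disp.valid & sheet_render.truth_mask])
        assert med == pytest.approx(19.0, abs=0.5)

    def test_shift_equivariance(self, rng):
        """Translating both images identically leaves interior disparities
        unchanged (evaluated away from the rolled-in borders)."""
        base = textured(rng, (36, 51))
        left, right = base[:, :-3], base[:, 3:]
        p = SgmParams(block_size=5, disparity_range=(0, 6))
        d0 = compute_disparity(left, right, p)
        d1 = compute_disparity(np.roll(left, (2, 5), (0, 1)),
                               np.roll(right, (2, 5), (0, 1)), p)
        a = d0.values[8:-8, 10:-10]
        b = d1.values[10:-6, 15:-5]
        va = d0.valid[8:-8, 10:-10]
        vb = d1.valid[10:-6, 15:-5]
        same = (a == b) & va & vb
        assert same.sum() / max(1, (va & vb).sum()) > 0.95

    def test_pipeline_equals_reference_spot_check(self, rng):
        left = rng.integers(0, 255, (10, 12)).astype(np.uint8)
        right = rng.integers(0, 255, (10, 12)).astype(np.uint8)
        p = tiny_params(disparity_range=(0, 5))
        disp = compute_disparity(left, right, p)
        rv, rvalid = ref_compute_disparity(left, right, p)
        assert np.array_equal(disp.values, rv)
        assert np.array_equal(disp.valid, rvalid)


class TestMedianSceneDistance:
    CAM = CameraModel(500.0, 500.0, 24.0, 20.0, 0.095, 48, 40)

    def make_disp(self, values, valid):
        return DisparityMap(values, valid, (0, 48), 16)

    def test_constant_disparity_triangulates(self):
        d = self.make_disp(np.full((40, 48), 19.0), np.ones((40, 48), bool))
        est = median_scene_distance(d, self.CAM, (48, 40))
        assert est.available and est.depth_m == pytest.approx(2.5)

    def test_invalid_pixels_ignored(self, rng):
        values = np.full((40, 48), 19.0)
        valid = np.ones((40, 48), bool)
        corrupt = rng.random((40, 48)) < 0.4
        values[corrupt] = rng.uniform(0, 48, corrupt.sum())
        valid[corrupt] = False
        est = median_scene_distance(self.make_disp(values, valid), self.CAM, (48, 40))
        # sort-based median over the valid subset only
        assert est.median_disparity == pytest.approx(
            float(np.median(values[valid])))
        assert est.depth_m == pytest.approx(2.5)

    def test_all_invalid_is_range_unavailable(self):
        d = self.make_disp(np.full((40, 48), 19.0), np.zeros((40, 48), bool))
        est = median_scene_distance(d, self.CAM, (48, 40))
        assert not est.available and est.depth_m is None

    def test_oversized_crop_clipped_with_flag(self, caplog):
        d = self.make_disp(np.full((40, 48), 19.0), np.ones((40, 48), bool))
        with caplog.at_level("WARNING"):
            est = median_scene_distance(d, self.CAM, (600, 400))
        assert est.crop_clipped and est.depth_m == pytest.approx(2.5)
        assert any("clipping" in r.message for r in caplog.records)

    def test_crop_selects_center(self):
        values = np.full((40, 48), 30.0)
        values[10:30, 14:34] = 19.0  # central 20x20 crop region
        d = self.make_disp(values, np.ones((40, 48), bool))
        est = median_scene_distance(d, self.CAM, (20, 20))
        assert est.depth_m == pytest.approx(2.5)
        assert est.n_valid == 400


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        values = rng.uniform(0, 30, (12, 16))
        valid = rng.random((12, 16)) > 0.3
        d = DisparityMap(values, valid, (0, 32), 16)
        save_disparity(d, tmp_path / "d.png")
        back = load_disparity(tmp_path / "d.png")
        assert np.array_equal(back.valid, valid)
        # 1/16 px fixed point
        assert np.all(np.abs(back.values[valid] - values[valid]) <= 1 / 32 + 1e-9)
        assert back.disparity_range == (0, 32)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(block_size=0),
            dict(disparity_range=(5, 5)),
            dict(disparity_range=(-1, 5)),
            dict(penalty_small=10.0, penalty_large=5.0),
            dict(n_paths=3),
            dict(subpixel_method="spline"),
        ],
    )
    def test_bad_params_rejected(self, kw):
        with pytest.raises(ValueError):
            SgmParams(**kw)
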