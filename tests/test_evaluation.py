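"""Pearson scoring, validity thresholding, ROI summaries, model comparison."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxenc.evaluation import (
    EncodingResult,
    ROIMap,
    average_repeats,
    pearson,
    pearson_columns,
    roi_top_n_mean,
    scatter_compare,
    summarize_by_roi,
    valid_mask,
)


def _result(pcc, roi_map=None, ids=None, model_id=""):
    ids = ids or [f"v{i}" for i in range(len(pcc))]
    return EncodingResult(np.asarray(pcc, float), ids, roi_map, model_id)


class TestPearson:
    def test_perfect_and_anti_correlation(self, rng):
        v = rng.standard_normal(20)
        assert pearson(v, v) == pytest.approx(1.0)
        assert pearson(v, -v) == pytest.approx(-1.0)

    def test_hand_computed_covariance_formula(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        vh = np.array([1.0, 2.0, 3.0, 5.0])
        # direct covariance formula oracle
        num = np.sum((v - v.mean()) * (vh - vh.mean()))
        den = np.sqrt(np.sum((v - v.mean()) ** 2) * np.sum((vh - vh.mean()) ** 2))
        assert pearson(v, vh) == pytest.approx(num / den)

    def test_zero_variance_is_undefined(self):
        assert np.isnan(pearson(np.ones(5), np.arange(5.0)))
        assert np.isnan(pearson(np.arange(5.0), np.zeros(5)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pearson(np.ones(3), np.ones(4))

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=10.0),
           st.floats(min_value=-5.0, max_value=5.0),
           st.booleans())
    def test_affine_invariance_up_to_sign(self, a, c, flip):
        rng = np.random.default_rng(5)
        v = rng.standard_normal(30)
        vh = rng.standard_normal(30)
        scale = -a if flip else a
        base = pearson(v, vh)
        assert pearson(scale * v + c, vh) == pytest.approx(np.sign(scale) * base, abs=1e-9)

    def test_columnwise_agrees_with_scalar(self, rng):
        V = rng.standard_normal((12, 5))
        Vh = rng.standard_normal((12, 5))
        cols = pearson_columns(V, Vh)
        for j in range(5):
            assert cols[j] == pytest.approx(pearson(V[:, j], Vh[:, j]))


class TestValidMask:
    def test_strictly_greater_than_threshold(self):
        mask, count = valid_mask(np.array([0.40, 0.41, 0.42]))
        assert mask.tolist() == [False, False, True]
        assert count == 1

    def test_undefined_is_invalid(self):
        mask, count = valid_mask(np.array([np.nan, np.nan]))
        assert count == 0

    def test_count_matches_brute_force(self, rng):
        pcc = rng.uniform(-1, 1, 500)
        pcc[rng.choice(500, 20, replace=False)] = np.nan
        _, count = valid_mask(pcc, 0.2)
        brute = sum(1 for p in pcc if np.isfinite(p) and p > 0.2)
        assert count == brute

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            valid_mask(np.zeros(3), threshold=1.0)


class TestROIMap:
    def test_groups_follow_definitions(self):
        m = ROIMap({"V1": [1], "V2": [2], "V3": [3], "V4": [4],
                    "LOC": [5], "FFA": [6], "PPA": [7]})
        assert set(m.members("LVC")) == {1, 2, 3}
        assert set(m.members("HVC")) == {5, 6, 7}
        assert set(m.members("VC")) == set(range(1, 8))

    def test_voxel_in_two_regions_rejected(self):
        with pytest.raises(ValueError, match="both"):
            ROIMap({"V1": [1, 2], "V2": [2]})

    def test_reserved_group_names_rejected(self):
        with pytest.raises(ValueError, match="reserved"):
            ROIMap({"LVC": [1]})

    def test_unknown_roi_rejected(self):
        with pytest.raises(KeyError):
            ROIMap({"V1": [1]}).members("V9")


class TestTopNMean:
    def test_small_roi_arithmetic(self):
        m = ROIMap({"V1": ["a", "b", "c"]})
        res = _result([0.1, 0.2, 0.3], m, ["a", "b", "c"])
        assert roi_top_n_mean(res, "V1", n=2) == pytest.approx(0.25)

    def test_constant_roi_returns_constant(self):
        m = ROIMap({"V1": ["a", "b", "c"]})
        res = _result([0.3, 0.3, 0.3], m, ["a", "b", "c"])
        for n in (1, 2, 100):
            assert roi_top_n_mean(res, "V1", n=n) == pytest.approx(0.3)

    def test_matches_sort_and_slice_oracle(self, rng):
        ids = [f"v{i}" for i in range(1000)]
        m = ROIMap({"V1": ids[:600], "V2": ids[600:]})
        pcc = rng.uniform(-1, 1, 1000)
        res = _result(pcc, m, ids)
        oracle = np.mean(sorted(pcc[:600], reverse=True)[:100])
        assert roi_top_n_mean(res, "V1", 100) == pytest.approx(oracle)

    def test_adding_high_voxel_cannot_decrease(self, rng):
        ids = [f"v{i}" for i in range(50)]
        pcc = rng.uniform(-1, 1, 50)
        m = ROIMap({"V1": ids})
        before = roi_top_n_mean(_result(pcc, m, ids), "V1", 10)
        nth = sorted(pcc, reverse=True)[9]
        m2 = ROIMap({"V1": ids + ["new"]})
        after = roi_top_n_mean(
            _result(np.append(pcc, nth + 0.05), m2, ids + ["new"]), "V1", 10
        )
        assert after >= before


class TestScatterCompare:
    def test_equal_models_have_no_red_or_blue(self, rng):
        pcc = rng.uniform(0, 1, 20)
        _, counts = scatter_compare(_result(pcc), _result(pcc.copy()))
        assert counts["red"] == 0 and counts["blue"] == 0

    def test_dominant_model_is_all_red(self):
        a = _result(np.zeros(10))
        b = _result(np.full(10, 0.9))
        _, counts = scatter_compare(a, b)
        assert counts["red"] == 10

    def test_neither_valid_is_black(self):
        a = _result([0.1, 0.2])
        b = _result([0.2, 0.1])
        _, counts = scatter_compare(a, b)
        assert counts["black"] == 2

    def test_counts_match_brute_force(self, rng):
        pa = rng.uniform(-1, 1, 1000)
        pb = rng.uniform(-1, 1, 1000)
        pa[rng.choice(1000, 30, replace=False)] = np.nan
        _, counts = scatter_compare(_result(pa), _result(pb), threshold=0.41)
        brute = {"red": 0, "blue": 0, "black": 0, "tie": 0}
        for x, y in zip(pa, pb):
            vx = np.isfinite(x) and x > 0.41
            vy = np.isfinite(y) and y > 0.41
            xs = x if np.isfinite(x) else -np.inf
            ys = y if np.isfinite(y) else -np.inf
            if not vx and not vy:
                brute["black"] += 1
            elif ys > xs:
                brute["red"] += 1
            elif xs > ys:
                brute["blue"] += 1
            else:
                brute["tie"] += 1
        assert counts == brute

    def test_voxel_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scatter_compare(_result([0.5], ids=["a"]), _result([0.5], ids=["b"]))


class TestAverageRepeats:
    def test_identical_repeats_average_to_themselves(self):
        row = np.array([1.0, 2.0, 3.0])
        R = np.tile(row, (35, 1))
        out, images = average_repeats(R, np.zeros(35, dtype=int))
        assert out.shape == (1, 3) and np.allclose(out[0], row)

    def test_opposite_repeats_cancel(self):
        x = np.array([[1.0, -2.0], [-1.0, 2.0]])
        out, _ = average_repeats(x, np.array([0, 0]))
        assert np.allclose(out, 0.0)

    def test_matches_groupby_oracle(self, rng):
        R = rng.standard_normal((60, 4))
        pres = rng.integers(0, 6, 60)
        out, images = average_repeats(R, pres)
        for gi, img in enumerate(images):
            assert np.allclose(out[gi], R[pres == img].mean(axis=0))

    def test_missing_image_rejected(self):
        with pytest.raises(ValueError, match="zero trials"):
            average_repeats(np.ones((4, 2)), np.array([0, 0, 1, 1]),
                            expected_images=[0, 1, 2])


def test_summarize_by_roi_includes_groups(rng):
    ids = [f"v{i}" for i in range(14)]
    base = {r: ids[2 * i : 2 * i + 2]
            for i, r in enumerate(("V1", "V2", "V3", "V4", "LOC", "FFA", "PPA"))}
    res = _result(rng.uniform(-1, 1, 14), ROIMap(base), ids)
    df = summarize_by_roi(res, n=2)
    assert set(df["roi"]) == {"V1", "V2", "V3", "V4", "LOC", "FFA", "PPA",
                              "LVC", "HVC", "VC"}
    assert (df[df["roi"] == "VC"]["n_voxels"] == 14).all()
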