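"""Synthetic dataset generator: images, ground truth, responses, fixtures."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from voxenc.mapping import DesignMatrix
from voxenc.synthetic import (
    SyntheticDatasetSpec,
    gen_ground_truth,
    gen_images,
    gen_responses,
    make_roi_map,
    reduced_spec,
    wellposed_spec,
)


class TestSpec:
    def test_defaults_mirror_study_conditions(self):
        spec = SyntheticDatasetSpec()
        assert spec.n_train == 1200
        assert spec.n_categories == 150 and spec.images_per_category == 8
        assert spec.n_test == 50 and spec.test_repeats == 35
        assert spec.image_size == 224

    def test_train_count_is_categories_times_images(self):
        spec = SyntheticDatasetSpec(n_categories=12, images_per_category=5)
        assert spec.n_train == 60

    def test_json_round_trip(self):
        spec = reduced_spec(seed=9)
        assert SyntheticDatasetSpec.from_json(spec.to_json()) == spec

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SyntheticDatasetSpec(n_categories=0)
        with pytest.raises(ValueError):
            SyntheticDatasetSpec(noise_sigma=-1.0)


class TestImages:
    def test_counts_follow_spec(self):
        spec = SyntheticDatasetSpec(image_size=16)  # full counts, small pixels
        train, train_cat, test, test_cat = gen_images(spec)
        assert train.shape == (1200, 3, 16, 16)
        assert test.shape == (50, 3, 16, 16)
        assert len(np.unique(train_cat)) == 150
        # test categories are held out from training
        assert set(test_cat).isdisjoint(set(train_cat))

    def test_same_seed_is_bitwise_identical(self):
        spec = reduced_spec(seed=4)
        a = gen_images(spec)
        b = gen_images(spec)
        assert (a[0] == b[0]).all() and (a[2] == b[2]).all()

    def test_within_category_images_more_similar_than_between(self):
        spec = reduced_spec(seed=3, n_categories=6, images_per_category=4)
        train, cats, _, _ = gen_images(spec)
        flat = train.reshape(train.shape[0], -1)
        corr = np.corrcoef(flat)
        within, between = [], []
        for i in range(len(cats)):
            for j in range(i + 1, len(cats)):
                (within if cats[i] == cats[j] else between).append(corr[i, j])
        assert np.mean(within) > np.mean(between)

    def test_values_lie_in_unit_interval(self):
        train, _, _, _ = gen_images(reduced_spec(seed=1))
        assert train.min() >= 0.0 and train.max() <= 1.0


@pytest.fixture(scope="module")
def small_problem():
    rng = np.random.default_rng(0)
    spec = reduced_spec(seed=0, n_voxels_per_roi=1, sparsity=3)
    F_train = DesignMatrix(rng.standard_normal((spec.n_train, 40)), fingerprint="fp")
    F_test = DesignMatrix(rng.standard_normal((spec.n_test, 40)), fingerprint="fp")
    return spec, F_train, F_test


class TestGroundTruthAndResponses:

    def test_supports_have_configured_sparsity(self, small_problem):
        spec, F_train, _ = small_problem
        truth = gen_ground_truth(F_train, spec)
        assert all(s.size == spec.sparsity for s in truth.supports)

    def test_noiseless_responses_are_exactly_linear(self, small_problem):
        spec, F_train, F_test = small_problem
        spec0 = dataclasses.replace(spec, noise_sigma=0.0)
        truth = gen_ground_truth(F_train, spec0)
        train, test, pres = gen_responses(F_train, F_test, truth, spec0)
        assert np.allclose(train, F_train.X @ truth.weights + truth.intercepts)
        assert np.allclose(test, (F_test.X @ truth.weights + truth.intercepts)[pres])

    def test_test_trial_count_is_images_times_repeats(self, small_problem):
        spec, F_train, F_test = small_problem
        truth = gen_ground_truth(F_train, spec)
        _, test, pres = gen_responses(F_train, F_test, truth, spec)
        assert test.shape[0] == spec.n_test * 35
        assert (np.bincount(pres) == 35).all()

    def test_noise_variance_matches_sigma_squared(self):
        """Sample noise variance at 1750 trials sits within 3 SE of sigma^2."""
        rng = np.random.default_rng(7)
        spec = reduced_spec(seed=7, n_test=50, test_repeats=35,
                            n_voxels_per_roi=1, sparsity=3, noise_sigma=0.8)
        F_train = DesignMatrix(rng.standard_normal((spec.n_train, 30)), fingerprint="f")
        F_test = DesignMatrix(rng.standard_normal((50, 30)), fingerprint="f")
        truth = gen_ground_truth(F_train, spec)
        _, test, pres = gen_responses(F_train, F_test, truth, spec)
        clean = (F_test.X @ truth.weights + truth.intercepts)[pres]
        noise = test - clean
        n = noise.shape[0]
        assert n == 1750
        se = spec.noise_sigma**2 * np.sqrt(2.0 / (n - 1))
        for j in range(noise.shape[1]):
            assert abs(noise[:, j].var(ddof=1) - spec.noise_sigma**2) < 3 * se

    def test_fingerprint_mismatch_rejected(self, small_problem):
        spec, F_train, F_test = small_problem
        truth = gen_ground_truth(F_train, spec)
        other = DesignMatrix(F_train.X, fingerprint="other")
        with pytest.raises(ValueError, match="fingerprint"):
            gen_responses(other, F_test, truth, spec)

    def test_signal_is_scaled_to_unit_variance(self, small_problem):
        spec, F_train, _ = small_problem
        truth = gen_ground_truth(F_train, spec)
        signal = F_train.X @ truth.weights
        assert np.allclose(signal.std(axis=0), 1.0)


class TestFixtureBundle:
    def test_bundle_is_complete(self, fixture_bundle):
        import os

        spec, paths = fixture_bundle
        for key in ("features_train", "features_test", "responses_train",
                    "responses_test", "rois", "truth", "spec"):
            assert os.path.exists(paths[key]), key

    def test_roi_map_covers_all_voxels(self, fixture_bundle):
        spec, paths = fixture_bundle
        roi_map = make_roi_map(spec)
        assert len(roi_map.members("VC")) == spec.n_voxels

    def test_two_seeds_differ_in_responses_not_shapes(self, tmp_path):
        from voxenc.io_utils import read_responses
        from voxenc.synthetic import make_fixture

        a = make_fixture(reduced_spec(seed=1), tmp_path / "a", write_images=False)
        b = make_fixture(reduced_spec(seed=2), tmp_path / "b", write_images=False)
        Ra, _, _ = read_responses(a["responses_train"])
        Rb, _, _ = read_responses(b["responses_train"])
        assert Ra.shape == Rb.shape
        assert not np.allclose(Ra, Rb)

    def test_wellposed_spec_exceeds_feature_count(self):
        # the point of the preset: more training samples than merged features
        from voxenc.backbones import build_replknet, build_vgg16

        spec = wellposed_spec()
        vgg = build_vgg16("reduced", input_size=spec.image_size)
        replk = build_replknet("reduced", input_size=spec.image_size)
        n_features = sum(int(np.prod(s)) for s in vgg.tap_shapes().values())
        n_features += sum(int(np.prod(s)) for s in replk.tap_shapes().values())
        n_features += int(np.prod(replk.tap_shapes()["stage4"]))  # normalized copy
        assert spec.n_train - 1 >= n_features
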