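"""Shared fixtures: tiny graphs and desk-scale synthetic bundles."""

from __future__ import annotations

import numpy as np
import pytest

from voxenc.backbones import build_replknet, build_vgg16
from voxenc.synthetic import (
    extract_merged,
    gen_images,
    quantize_images,
    reduced_backbones,
    reduced_spec,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reduced_vgg():
    return build_vgg16("reduced", seed=0)


@pytest.fixture(scope="session")
def reduced_replk():
    return build_replknet("reduced", seed=1)


@pytest.fixture(scope="session")
def small_images():
    """Eight 32x32 RGB images from two synthetic stimulus categories."""
    spec = reduced_spec(seed=7, n_categories=2, images_per_category=4, n_test=1)
    train, cats, _, _ = gen_images(spec)
    return quantize_images(train), cats


@pytest.fixture(scope="session")
def reduced_features(reduced_vgg, reduced_replk, small_images):
    """Merged M features for the small image set."""
    images, _ = small_images
    F, meta = extract_merged(reduced_vgg, reduced_replk, images)
    return F, meta


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """A complete reduced fixture bundle on disk (written once per session)."""
    from voxenc.synthetic import make_fixture

    spec = reduced_spec(seed=11)
    out = tmp_path_factory.mktemp("fixture")
    paths = make_fixture(spec, out)
    return spec, paths
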