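"""Synthetic stimulus/response datasets with known ground truth.

Emulates the structure of the image-presentation fMRI experiment the
encoding pipeline targets: a training set of category-organized natural-image
stimuli (default 1200 images, 150 categories x 8), a test set of images from
held-out categories (default 50) each presented many times (default 35), and
voxel responses that are sparse linear functions of the image features plus
Gaussian noise.  Images are category-specific Gabor-texture mixtures, so
categories are discriminable by convolutional features; all randomness flows
through one seeded generator.

The generator gives every downstream stage a desk-scale test bed with known
per-voxel weights — it does not attempt retinotopy, hemodynamics, or fMRI
time-series structure.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .backbones import IMAGE_MEAN, IMAGE_STD, build_replknet, build_vgg16
from .evaluation import BASE_ROIS, ROIMap
from .feature_space import extract_R, extract_V, flatten_stack, merge_features
from .mapping import DesignMatrix


@dataclass
class SyntheticDatasetSpec:
    """Study-shaped dataset parameters.

    Defaults mirror the experimental conditions the pipeline assumes: 1200
    training images in 150 categories of 8, 50 test images from held-out
    categories shown 35 times each, 224x224 RGB stimuli.  ``noise_sigma`` is
    the trial-noise standard deviation in units of the per-voxel signal
    standard deviation (signal is scaled to unit variance).
    """

    n_categories: int = 150
    images_per_category: int = 8
    n_test: int = 50
    test_repeats: int = 35
    image_size: int = 224
    n_voxels_per_roi: int = 100
    rois: tuple[str, ...] = BASE_ROIS
    sparsity: int = 10
    noise_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_categories",
            "images_per_category",
            "n_test",
            "test_repeats",
            "image_size",
            "n_voxels_per_roi",
            "sparsity",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def n_train(self) -> int:
        return self.n_categories * self.images_per_category

    @property
    def n_voxels(self) -> int:
        return self.n_voxels_per_roi * len(self.rois)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticDatasetSpec":
        d = json.loads(text)
        d["rois"] = tuple(d["rois"])
        return cls(**d)


def reduced_spec(seed: int = 0, **overrides) -> SyntheticDatasetSpec:
    """Desk-scale preset: 120 training images at 32x32, 2 voxels per ROI."""
    kw = dict(
        n_categories=30,
        images_per_category=4,
        n_test=10,
        test_repeats=35,
        image_size=32,
        n_voxels_per_roi=2,
        sparsity=10,
        noise_sigma=0.5,
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticDatasetSpec(**kw)


def wellposed_spec(seed: int = 0, **overrides) -> SyntheticDatasetSpec:
    """Preset with more training samples than merged reduced-backbone features.

    With m - 1 >= n the principal components span the entire feature space,
    so noiseless responses are exactly recoverable by the pipeline — the
    regime for exact end-to-end recovery checks.
    """
    kw = dict(
        n_categories=400,
        images_per_category=4,
        n_test=15,
        test_repeats=35,
        image_size=32,
        n_voxels_per_roi=2,
        sparsity=10,
        noise_sigma=0.0,
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticDatasetSpec(**kw)


@dataclass
class GroundTruth:
    """True sparse per-voxel weights over the (pre-PCA) feature space."""

    weights: np.ndarray       # (n_features, n_voxels), sparse columns
    intercepts: np.ndarray    # (n_voxels,)
    noise_sigma: float
    fingerprint: str

    def __post_init__(self) -> None:
        if self.weights.ndim != 2 or self.intercepts.shape != (self.weights.shape[1],):
            raise ValueError("inconsistent ground-truth shapes")

    @property
    def supports(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.weights[:, j]) for j in range(self.weights.shape[1])]


# ---------------------------------------------------------------------------
# images


def _gabor(size: int, theta: float, freq: float, phase: float,
           cy: float, cx: float, env_sigma: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    yy = (yy - cy) / size
    xx = (xx - cx) / size
    rot = xx * np.cos(theta) + yy * np.sin(theta)
    env = np.exp(-(xx**2 + yy**2) / (2 * env_sigma**2))
    return env * np.cos(2 * np.pi * freq * size * rot + phase)


def _category_params(rng: np.random.Generator, size: int, n_atoms: int = 3) -> dict:
    return {
        "theta": rng.uniform(0, np.pi, n_atoms),
        "freq": rng.uniform(0.05, 0.25, n_atoms),
        "phase": rng.uniform(0, 2 * np.pi, n_atoms),
        "cy": rng.uniform(0.3, 0.7, n_atoms) * size,
        "cx": rng.uniform(0.3, 0.7, n_atoms) * size,
        "env": rng.uniform(0.15, 0.35, n_atoms),
        "channel_w": rng.uniform(0.3, 1.0, (n_atoms, 3)),
    }


def _render(params: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.zeros((3, size, size))
    n_atoms = params["theta"].size
    amps = 1.0 + 0.4 * rng.standard_normal(n_atoms)
    for a in range(n_atoms):
        g = _gabor(size, params["theta"][a], params["freq"][a], params["phase"][a],
                   params["cy"][a], params["cx"][a], params["env"][a])
        img += amps[a] * params["channel_w"][a][:, None, None] * g[None]
    img += 0.05 * rng.standard_normal(img.shape)
    return 0.5 + 0.5 * np.tanh(img)  # squash into (0, 1)


def gen_images(spec: SyntheticDatasetSpec):
    """Seeded category-structured Gabor-texture stimuli.

    Returns ``(train_images, train_categories, test_images, test_categories)``
    with images as float arrays in (0, 1), shape ``(n, 3, size, size)``.
    Test categories are disjoint from training categories, as in the
    experimental design being emulated.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    cats = [_category_params(rng, size) for _ in range(spec.n_categories + spec.n_test)]

    train = np.empty((spec.n_train, 3, size, size))
    train_cat = np.repeat(np.arange(spec.n_categories), spec.images_per_category)
    for i, c in enumerate(train_cat):
        train[i] = _render(cats[c], size, rng)

    test = np.empty((spec.n_test, 3, size, size))
    test_cat = spec.n_categories + np.arange(spec.n_test)
    for i, c in enumerate(test_cat):
        test[i] = _render(cats[c], size, rng)
    return train, train_cat, test, test_cat


def quantize_images(images: np.ndarray) -> np.ndarray:
    """8-bit round trip, matching what PNG storage preserves."""
    return np.round(np.clip(images, 0, 1) * 255.0) / 255.0


# ---------------------------------------------------------------------------
# features and responses


def standardize_images(images: np.ndarray) -> np.ndarray:
    """Per-channel mean/std standardization of RGB input in [0, 1]."""
    return (images - IMAGE_MEAN[:, None, None]) / IMAGE_STD[:, None, None]


def extract_merged(vgg, replk, images: np.ndarray, batch: int = 64):
    """V + R extraction and merge over batches -> (DesignMatrix, layer meta)."""
    rows = []
    meta = None
    for at in range(0, images.shape[0], batch):
        chunk = standardize_images(images[at : at + batch])
        m = merge_features(extract_V(vgg, chunk), extract_R(replk, chunk))
        X, meta = flatten_stack(m)
        rows.append(X)
        fp = m.fingerprint
    X = np.concatenate(rows, axis=0)
    return DesignMatrix(X, fingerprint=_data_fingerprint(fp, meta)), meta


def _data_fingerprint(backbone_fp: str, meta) -> str:
    h = hashlib.sha256(repr((backbone_fp, meta)).encode())
    return h.hexdigest()[:16]


def gen_ground_truth(
    features_train: DesignMatrix, spec: SyntheticDatasetSpec,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Sparse random per-voxel weights over features with training variance.

    Supports are drawn uniformly among feature columns that vary across the
    training images; coefficients are two-sided uniform in +-[0.5, 2]; each
    voxel's weight vector is rescaled so the noiseless training signal has
    unit standard deviation, which makes ``noise_sigma`` directly
    interpretable as a noise-to-signal ratio.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    X = features_train.X
    stds = X.std(axis=0)
    alive = np.flatnonzero(stds > 1e-10 * max(stds.max(), 1e-30))
    if alive.size < spec.sparsity:
        raise ValueError("not enough varying features for the requested sparsity")
    n = X.shape[1]
    W = np.zeros((n, spec.n_voxels))
    for j in range(spec.n_voxels):
        sup = rng.choice(alive, size=spec.sparsity, replace=False)
        coef = rng.uniform(0.5, 2.0, spec.sparsity) * rng.choice([-1, 1], spec.sparsity)
        signal = X[:, sup] @ coef
        scale = signal.std()
        if scale == 0:
            scale = 1.0
        W[sup, j] = coef / scale
    b = rng.uniform(-0.5, 0.5, spec.n_voxels)
    return GroundTruth(W, b, spec.noise_sigma, features_train.fingerprint)


def gen_responses(
    features_train: DesignMatrix,
    features_test: DesignMatrix,
    truth: GroundTruth,
    spec: SyntheticDatasetSpec,
    rng: np.random.Generator | None = None,
):
    """Noisy linear voxel responses for train images and repeated test trials.

    Training responses are one trial per image; test responses replicate each
    test image ``test_repeats`` times with independent noise per trial, and a
    presentation map assigns each trial its image index.
    """
    if truth.fingerprint != features_train.fingerprint:
        raise ValueError(
            "feature fingerprint does not match the ground truth "
            f"({features_train.fingerprint} vs {truth.fingerprint})"
        )
    rng = rng or np.random.default_rng(spec.seed + 2)
    clean_train = features_train.X @ truth.weights + truth.intercepts
    train = clean_train + truth.noise_sigma * rng.standard_normal(clean_train.shape)

    clean_test = features_test.X @ truth.weights + truth.intercepts
    presentation = np.repeat(np.arange(features_test.n_samples), spec.test_repeats)
    trials = clean_test[presentation]
    test = trials + truth.noise_sigma * rng.standard_normal(trials.shape)
    return train, test, presentation


def make_roi_map(spec: SyntheticDatasetSpec) -> ROIMap:
    ids = [f"vox{idx:05d}" for idx in range(spec.n_voxels)]
    base = {
        roi: ids[i * spec.n_voxels_per_roi : (i + 1) * spec.n_voxels_per_roi]
        for i, roi in enumerate(spec.rois)
    }
    return ROIMap(base)


# ---------------------------------------------------------------------------
# fixture bundles


def reduced_backbones(spec: SyntheticDatasetSpec, seed: int | None = None):
    """Topology-faithful reduced V and R extractors sized for the fixture."""
    seed = spec.seed if seed is None else seed
    vgg = build_vgg16("reduced", seed=seed, input_size=spec.image_size)
    replk = build_replknet("reduced", seed=seed + 1, input_size=spec.image_size)
    return vgg, replk


def make_fixture(spec: SyntheticDatasetSpec, out_dir: str | Path,
                 write_images: bool = True) -> dict:
    """Generate a complete on-disk bundle for the encoding pipeline.

    Writes stimulus PNGs with a manifest, merged features for train and test
    images, train/test response containers, the ROI map, the ground truth and
    the dataset spec.  Returns the path dictionary.
    """
    from . import io_utils  # deferred: io_utils imports from this module's deps

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train, train_cat, test, test_cat = gen_images(spec)
    train = quantize_images(train)
    test = quantize_images(test)

    if write_images:
        _write_images(out, train, train_cat, test, test_cat)

    vgg, replk = reduced_backbones(spec)
    F_train, meta = extract_merged(vgg, replk, train)
    F_test, _ = extract_merged(vgg, replk, test)

    rng = np.random.default_rng(spec.seed + 1)
    truth = gen_ground_truth(F_train, spec, rng)
    resp_train, resp_test, presentation = gen_responses(F_train, F_test, truth, spec, rng)

    roi_map = make_roi_map(spec)
    ids = [f"vox{idx:05d}" for idx in range(spec.n_voxels)]

    paths = {
        "root": str(out),
        "images": str(out / "images"),
        "features_train": str(out / "features_train.h5"),
        "features_test": str(out / "features_test.h5"),
        "responses_train": str(out / "responses_train.h5"),
        "responses_test": str(out / "responses_test.h5"),
        "rois": str(out / "rois.json"),
        "truth": str(out / "truth.h5"),
        "spec": str(out / "spec.json"),
    }
    io_utils.save_design(paths["features_train"], F_train, meta)
    io_utils.save_design(paths["features_test"], F_test, meta)
    io_utils.save_responses(paths["responses_train"], resp_train, ids)
    io_utils.save_responses(paths["responses_test"], resp_test, ids, presentation)
    io_utils.write_roi_map(paths["rois"], roi_map)
    io_utils.save_ground_truth(paths["truth"], truth)
    Path(paths["spec"]).write_text(spec.to_json())
    return paths


def _write_images(out: Path, train, train_cat, test, test_cat) -> None:
    from PIL import Image

    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    rows = []
    for split, images, cats in (("train", train, train_cat), ("test", test, test_cat)):
        for i, (img, c) in enumerate(zip(images, cats)):
            name = f"{split}_{i:05d}.png"
            arr = np.round(img * 255).astype(np.uint8).transpose(1, 2, 0)
            Image.fromarray(arr).save(img_dir / name)
            rows.append((name, int(c), split))
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "category", "split"])
        writer.writerows(rows)
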