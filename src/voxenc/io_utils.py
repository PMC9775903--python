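"""On-disk containers and the end-to-end pipeline runner.

All large arrays travel in HDF5 containers with JSON sidecars for specs and
ROI maps.  Every artifact carries a fingerprint tying it to the backbone
configuration that produced it; the pipeline refuses mixed-provenance inputs
(e.g. test features from a different backbone than the fitted model).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import synthetic
from .evaluation import (
    EncodingResult,
    ROIMap,
    average_repeats,
    pearson_columns,
    summarize_by_roi,
)
from .mapping import (
    DesignMatrix,
    FitConfig,
    PCAModel,
    SparseLinearModel,
    fit_voxelwise,
    pca_fit,
    pca_transform,
    predict,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# design matrices


def save_design(path: str, F: DesignMatrix, layer_meta=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("M", data=F.X.astype(np.float32))
        f.attrs["fingerprint"] = F.fingerprint
        f.attrs["pca_applied"] = F.pca_applied
        if layer_meta is not None:
            f.attrs["layers"] = json.dumps(
                [(name, list(shape)) for name, shape in layer_meta]
            )


def load_design(path: str) -> DesignMatrix:
    with h5py.File(path, "r") as f:
        X = f["M"][...].astype(float)
        return DesignMatrix(
            X,
            fingerprint=str(f.attrs.get("fingerprint", "")),
            pca_applied=bool(f.attrs.get("pca_applied", False)),
        )


# ---------------------------------------------------------------------------
# responses


def save_responses(path, responses, voxel_ids, presentation=None) -> None:
    responses = np.asarray(responses, dtype=float)
    with h5py.File(path, "w") as f:
        f.create_dataset("responses", data=responses)
        f.create_dataset("voxel_ids", data=np.array(voxel_ids, dtype="S"))
        if presentation is not None:
            f.create_dataset("presentation", data=np.asarray(presentation))


def read_responses(path):
    """-> (trials x voxels matrix, voxel ids, presentation map or None)."""
    with h5py.File(path, "r") as f:
        if "responses" not in f or "voxel_ids" not in f:
            raise ValueError(f"{path}: missing 'responses' or 'voxel_ids' dataset")
        R = f["responses"][...].astype(float)
        ids = [s.decode() for s in f["voxel_ids"][...]]
        pres = f["presentation"][...] if "presentation" in f else None
    if not np.all(np.isfinite(R)):
        raise ValueError(f"{path}: non-finite response entries")
    if R.ndim != 2 or R.shape[1] != len(ids):
        raise ValueError(f"{path}: responses {R.shape} do not match {len(ids)} ids")
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate voxel ids")
    return R, ids, pres


# ---------------------------------------------------------------------------
# ROI maps


def write_roi_map(path, roi_map: ROIMap) -> None:
    Path(path).write_text(json.dumps(roi_map.base, indent=2))


def read_roi_map(path) -> ROIMap:
    """JSON text {"V1": [ids...], ...}; derived groups are never stored."""
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected an object of region -> id list")
    return ROIMap({str(k): list(v) for k, v in data.items()})


# ---------------------------------------------------------------------------
# ground truth


def save_ground_truth(path, truth: synthetic.GroundTruth) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=truth.weights)
        f.create_dataset("intercepts", data=truth.intercepts)
        f.attrs["noise_sigma"] = truth.noise_sigma
        f.attrs["fingerprint"] = truth.fingerprint


def load_ground_truth(path) -> synthetic.GroundTruth:
    with h5py.File(path, "r") as f:
        return synthetic.GroundTruth(
            f["weights"][...],
            f["intercepts"][...],
            float(f.attrs["noise_sigma"]),
            str(f.attrs["fingerprint"]),
        )


# ---------------------------------------------------------------------------
# fitted models


def save_model(path, pca: PCAModel, models: list[SparseLinearModel],
               cfg: FitConfig, fingerprint: str = "") -> None:
    """Layout: /pca/{mean,components,variance}, /voxels/<i>/{w,b,support}."""
    with h5py.File(path, "w") as f:
        g = f.create_group("pca")
        g.create_dataset("mean", data=pca.mean)
        g.create_dataset("components", data=pca.components)
        g.create_dataset("variance", data=pca.explained_variance)
        vox = f.create_group("voxels")
        for i, mdl in enumerate(models):
            gi = vox.create_group(str(i))
            gi.create_dataset("w", data=mdl.w)
            gi.create_dataset("b", data=mdl.b)
            gi.create_dataset("support", data=mdl.support)
        f.attrs["meta"] = json.dumps(
            {"fit_config": asdict(cfg), "fingerprint": fingerprint,
             "n_voxels": len(models)}
        )


def load_model(path):
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        pca = PCAModel(
            f["pca/mean"][...], f["pca/components"][...], f["pca/variance"][...],
            fingerprint=meta.get("fingerprint", ""),
        )
        models = []
        for i in range(meta["n_voxels"]):
            gi = f[f"voxels/{i}"]
            models.append(
                SparseLinearModel(
                    gi["w"][...], float(gi["b"][...]), gi["support"][...].astype(int)
                )
            )
        cfg = FitConfig(**meta["fit_config"])
    return pca, models, cfg, meta.get("fingerprint", "")


# ---------------------------------------------------------------------------
# image loading


def load_image_dir(image_dir, manifest_path=None):
    """PNG/JPEG directory + manifest CSV -> (train array, test array, names)."""
    import pandas as pd
    from PIL import Image

    image_dir = Path(image_dir)
    manifest_path = manifest_path or image_dir.parent / "manifest.csv"
    manifest = pd.read_csv(manifest_path)
    out = {}
    for split in ("train", "test"):
        rows = manifest[manifest["split"] == split]
        imgs = []
        for name in rows["filename"]:
            arr = np.asarray(Image.open(image_dir / name).convert("RGB"), dtype=float)
            imgs.append(arr.transpose(2, 0, 1) / 255.0)
        out[split] = np.stack(imgs) if imgs else None
    return out["train"], out["test"], manifest


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """Everything one end-to-end encoding run needs, serializable to JSON."""

    fixture_dir: str
    out_dir: str
    backbone_seed: int | None = None
    # None derives K from the fitted PCA dimension (K = ceil(k / 2)), so the
    # 2K support budget can cover every retained component — the right choice
    # when the fit must be able to reproduce the training data exactly
    sparsity: int | None = 20
    tol: float = 1e-6
    max_iter: int = 50
    top_n: int = 100
    threshold: float = 0.41
    average_test_repeats: bool = True
    use_stored_features: bool = True
    seed: int = 0

    def fit_config(self, pca_k: int) -> FitConfig:
        if self.sparsity is None:
            k = max(1, (pca_k + 1) // 2)
        else:
            k = min(self.sparsity, max(1, pca_k))
        return FitConfig(k, self.tol, self.max_iter, self.seed)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Extract -> merge -> PCA -> fit -> predict -> evaluate, with a manifest.

    Reads a fixture bundle (as written by :func:`voxenc.synthetic.make_fixture`
    or assembled by hand in the same layout), writes per-voxel results, the
    per-ROI summary and a run manifest into ``config.out_dir``.
    """
    fixture = Path(config.fixture_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = synthetic.SyntheticDatasetSpec.from_json((fixture / "spec.json").read_text())
    stage_times: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()

            def __exit__(self_, *exc):
                stage_times[name] = round(time.perf_counter() - self_.t0, 3)
                if exc[0] is not None:
                    logger.error("pipeline stage %r failed", name)

        return _T()

    with stage("features"):
        if config.use_stored_features and (fixture / "features_train.h5").exists():
            F_train = load_design(fixture / "features_train.h5")
            F_test = load_design(fixture / "features_test.h5")
        else:
            train_imgs, test_imgs, _ = load_image_dir(fixture / "images")
            vgg, replk = synthetic.reduced_backbones(spec, seed=config.backbone_seed)
            F_train, _ = synthetic.extract_merged(vgg, replk, train_imgs)
            F_test, _ = synthetic.extract_merged(vgg, replk, test_imgs)
        if F_train.fingerprint != F_test.fingerprint:
            raise ValueError(
                "train/test features come from different extractors: "
                f"{F_train.fingerprint} vs {F_test.fingerprint}"
            )

    with stage("responses"):
        R_train, ids, _ = read_responses(fixture / "responses_train.h5")
        R_test, ids_test, presentation = read_responses(fixture / "responses_test.h5")
        if ids != ids_test:
            raise ValueError("train/test voxel ids differ")
        roi_map = read_roi_map(fixture / "rois.json")

    with stage("pca"):
        pca = pca_fit(F_train)
        Z_train = pca_transform(pca, F_train)
        Z_test = pca_transform(pca, F_test)

    with stage("fit"):
        cfg = config.fit_config(pca.k)
        models = fit_voxelwise(Z_train, R_train, cfg)
        model_path = out / "model.h5"
        save_model(model_path, pca, models, cfg, F_train.fingerprint)

    with stage("evaluate"):
        V_hat = predict(models, Z_test)
        if config.average_test_repeats:
            if presentation is None:
                raise ValueError(
                    "test responses carry no presentation map; cannot average repeats"
                )
            V_obs, _ = average_repeats(R_test, presentation)
        else:
            V_obs = R_test
            V_hat = V_hat[presentation] if presentation is not None else V_hat
        pcc = pearson_columns(V_obs, V_hat)
        result = EncodingResult(pcc, ids, roi_map, model_id="mixed",
                                threshold=config.threshold)
        result.to_frame().to_csv(out / "results.csv", index=False)
        summary = summarize_by_roi(result, n=config.top_n)
        summary.to_csv(out / "summary.csv", index=False)

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "feature_fingerprint": F_train.fingerprint,
        "pca_components": int(pca.k),
        "n_voxels": len(ids),
        "n_valid": int(result.valid.sum()),
        "mean_pcc": float(np.nanmean(pcc)),
        "min_pcc": float(np.nanmin(pcc)),
        "stage_seconds": stage_times,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline finished: %s", manifest)
    return {
        "result": result,
        "summary": summary,
        "manifest": manifest,
        "out_dir": str(out),
    }
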