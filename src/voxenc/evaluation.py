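"""Scoring encoding models: per-voxel Pearson correlation and ROI summaries.

Prediction accuracy is the sample Pearson correlation Pcc = cor(v, v_hat)
between observed and predicted voxel responses on the test images.  Voxels
with Pcc strictly greater than 0.41 count as validly predicted; per-ROI
performance is summarized as the mean of the top-n (default 100) voxel
correlations; two models are compared voxel-by-voxel with a categorized
scatter (better / worse / neither-valid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_THRESHOLD = 0.41

BASE_ROIS = ("V1", "V2", "V3", "V4", "LOC", "FFA", "PPA")
ROI_GROUPS = {
    "LVC": ("V1", "V2", "V3"),
    "HVC": ("LOC", "FFA", "PPA"),
    "VC": ("V1", "V2", "V3", "V4", "LOC", "FFA", "PPA"),
}


@dataclass
class ROIMap:
    """Voxel-id lists per base region, with the standard derived groups.

    LVC = V1+V2+V3, HVC = LOC+FFA+PPA, VC = LVC+V4+HVC; derived groups are
    computed, never user-supplied.
    """

    base: dict[str, list]

    def __post_init__(self) -> None:
        for name in self.base:
            if name in ROI_GROUPS:
                raise ValueError(f"{name} is a reserved derived group name")
        seen: dict = {}
        for name, ids in self.base.items():
            for v in ids:
                if v in seen:
                    raise ValueError(
                        f"voxel {v!r} assigned to both {seen[v]} and {name}"
                    )
                seen[v] = name

    def members(self, roi: str) -> list:
        if roi in self.base:
            return list(self.base[roi])
        if roi in ROI_GROUPS:
            out: list = []
            for base_name in ROI_GROUPS[roi]:
                out.extend(self.base.get(base_name, []))
            return out
        raise KeyError(f"unknown ROI {roi!r}")

    def region_of(self) -> dict:
        return {v: name for name, ids in self.base.items() for v in ids}


@dataclass
class EncodingResult:
    """Per-voxel correlations with validity flags for one fitted model."""

    pcc: np.ndarray
    voxel_ids: list
    roi_map: ROIMap | None = None
    model_id: str = ""
    threshold: float = VALID_THRESHOLD
    valid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pcc = np.asarray(self.pcc, dtype=float)
        if len(self.voxel_ids) != self.pcc.shape[0]:
            raise ValueError("voxel_ids length must match pcc length")
        finite = np.isfinite(self.pcc)
        if np.any(np.abs(self.pcc[finite]) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        self.valid = valid_mask(self.pcc, self.threshold)[0]

    def to_frame(self) -> pd.DataFrame:
        region = self.roi_map.region_of() if self.roi_map else {}
        return pd.DataFrame(
            {
                "voxel_id": self.voxel_ids,
                "roi": [region.get(v, "") for v in self.voxel_ids],
                "pcc": self.pcc,
                "valid": self.valid,
                "model_id": self.model_id,
            }
        )


def pearson(v: np.ndarray, v_hat: np.ndarray) -> float:
    """Sample Pearson correlation; NaN when either vector has no variance."""
    v = np.asarray(v, dtype=float).ravel()
    v_hat = np.asarray(v_hat, dtype=float).ravel()
    if v.shape != v_hat.shape:
        raise ValueError(f"length mismatch: {v.shape[0]} vs {v_hat.shape[0]}")
    if v.shape[0] < 2:
        raise ValueError("need at least two observations")
    a = v - v.mean()
    b = v_hat - v_hat.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return float("nan")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def pearson_columns(V: np.ndarray, V_hat: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations (one per voxel)."""
    V = np.asarray(V, dtype=float)
    V_hat = np.asarray(V_hat, dtype=float)
    if V.shape != V_hat.shape:
        raise ValueError(f"shape mismatch: {V.shape} vs {V_hat.shape}")
    A = V - V.mean(axis=0)
    B = V_hat - V_hat.mean(axis=0)
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->j", A, B) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    return np.clip(r, -1.0, 1.0)


def valid_mask(
    pcc: np.ndarray, threshold: float = VALID_THRESHOLD
) -> tuple[np.ndarray, int]:
    """Strict threshold rule: valid iff Pcc > threshold; NaN is invalid."""
    if not -1.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (-1, 1)")
    pcc = np.asarray(pcc, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = np.greater(pcc, threshold) & np.isfinite(pcc)
    return mask, int(mask.sum())


def roi_top_n_mean(result: EncodingResult, roi: str, n: int = 100) -> float:
    """Mean of the n largest voxel correlations within an ROI.

    Uses all voxels if the ROI holds fewer than n; undefined correlations are
    excluded; ties break deterministically by voxel index.
    """
    if result.roi_map is None:
        raise ValueError("result carries no ROI map")
    members = set(result.roi_map.members(roi))
    if not members:
        raise ValueError(f"ROI {roi!r} is empty")
    idx = np.array([i for i, v in enumerate(result.voxel_ids) if v in members])
    if idx.size == 0:
        raise ValueError(f"no voxels of ROI {roi!r} present in the result")
    vals = result.pcc[idx]
    keep = np.isfinite(vals)
    vals, idx = vals[keep], idx[keep]
    if vals.size == 0:
        return float("nan")
    order = np.lexsort((idx, -vals))  # by decreasing pcc, then voxel index
    return float(vals[order[:n]].mean())


def scatter_compare(
    result_a: EncodingResult,
    result_b: EncodingResult,
    threshold: float = VALID_THRESHOLD,
):
    """Voxel-by-voxel model comparison, as in a correlation scatter plot.

    Categories: ``red`` where model B predicts better (and at least one model
    is valid), ``blue`` where model A does, ``black`` where neither reaches a
    valid correlation, and ``tie`` for exactly equal correlations with at
    least one valid.  Undefined correlations rank below every number.
    """
    if list(result_a.voxel_ids) != list(result_b.voxel_ids):
        raise ValueError("results cover different voxel sets")
    a = np.where(np.isfinite(result_a.pcc), result_a.pcc, -np.inf)
    b = np.where(np.isfinite(result_b.pcc), result_b.pcc, -np.inf)
    valid_a = valid_mask(result_a.pcc, threshold)[0]
    valid_b = valid_mask(result_b.pcc, threshold)[0]
    any_valid = valid_a | valid_b
    cats = np.full(a.shape, "black", dtype=object)
    cats[any_valid & (b > a)] = "red"
    cats[any_valid & (a > b)] = "blue"
    cats[any_valid & (a == b)] = "tie"
    counts = {c: int(np.sum(cats == c)) for c in ("red", "blue", "black", "tie")}
    points = pd.DataFrame(
        {
            "voxel_id": result_a.voxel_ids,
            "pcc_a": result_a.pcc,
            "pcc_b": result_b.pcc,
            "category": cats,
        }
    )
    return points, counts


def average_repeats(
    responses: np.ndarray,
    presentation: np.ndarray,
    expected_images: list | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average trial responses across repeated presentations of each image.

    ``presentation`` assigns each trial (row) an image identifier; rows of
    the output follow sorted image identifiers, which are returned alongside.
    """
    responses = np.asarray(responses, dtype=float)
    presentation = np.asarray(presentation)
    if presentation.shape[0] != responses.shape[0]:
        raise ValueError("presentation map must assign every trial an image")
    images = np.unique(presentation)
    if expected_images is not None:
        missing = sorted(set(expected_images) - set(images.tolist()))
        if missing:
            raise ValueError(f"images with zero trials: {missing}")
    df = pd.DataFrame(responses)
    df["__image__"] = presentation
    means = df.groupby("__image__", sort=True).mean()
    return means.to_numpy(), means.index.to_numpy()


def summarize_by_roi(
    result: EncodingResult, n: int = 100, rois: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Per-ROI table of top-n mean Pcc, voxel counts and valid counts."""
    if result.roi_map is None:
        raise ValueError("result carries no ROI map")
    names = list(rois) if rois else [
        r for r in BASE_ROIS if result.roi_map.base.get(r)
    ] + [g for g in ("LVC", "HVC", "VC") if result.roi_map.members(g)]
    rows = []
    region_members = {name: set(result.roi_map.members(name)) for name in names}
    for name in names:
        idx = np.array(
            [i for i, v in enumerate(result.voxel_ids) if v in region_members[name]],
            dtype=int,
        )
        if idx.size == 0:
            continue
        rows.append(
            {
                "roi": name,
                "n_voxels": int(idx.size),
                "n_valid": int(result.valid[idx].sum()),
                f"top{n}_mean_pcc": roi_top_n_mean(result, name, n),
            }
        )
    return pd.DataFrame(rows)
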