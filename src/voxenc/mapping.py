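"""Feature-to-voxel linear system: PCA reduction, then per-voxel sparse fits.

The encoding model is V = Fw + b per voxel: image features F (m samples x n
features, typically n >> m) predict one voxel's responses through a sparse
linear weight w and intercept b.  Features are first reduced to at most m-1
principal components; the sparse weights are then found with Regularized
Orthogonal Matching Pursuit (ROMP), the greedy pursuit of Needell &
Vershynin: each iteration correlates the residual with all columns, keeps
the K largest-magnitude correlations, selects among them the maximal-energy
subset whose magnitudes lie within a factor of two of each other, adds that
subset to the support, and re-solves least squares on the support.

The intercept is handled by centering (numerically equivalent to an explicit
all-ones column and keeps the PCA well-defined).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

RANK_RTOL = 1e-10  # singular values below this fraction of the largest are noise


@dataclass
class DesignMatrix:
    """m x n feature matrix with provenance metadata."""

    X: np.ndarray
    sample_ids: list | None = None
    fingerprint: str = ""
    pca_applied: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.X.shape[0] < 2:
            raise ValueError("need at least two samples")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("design matrix must be finite")
        if self.sample_ids is not None and len(self.sample_ids) != self.X.shape[0]:
            raise ValueError("sample_ids length must equal the row count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class PCAModel:
    mean: np.ndarray          # (n,)
    components: np.ndarray    # (n, k), orthonormal columns
    explained_variance: np.ndarray  # (k,), decreasing
    fingerprint: str = ""

    @property
    def k(self) -> int:
        return self.components.shape[1]


@dataclass
class SparseLinearModel:
    """One voxel's fitted weights: w over the reduced features, intercept b."""

    w: np.ndarray
    b: float
    support: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nz = np.flatnonzero(self.w)
        if not np.isin(nz, self.support).all():
            raise ValueError("nonzero weights outside the declared support")


@dataclass
class FitConfig:
    """ROMP hyperparameters.

    ``sparsity`` is the per-iteration candidate count K (the final support is
    bounded by 2K); ``tol`` is the residual-norm stopping tolerance relative
    to the norm of the centered response; defaults follow common
    sparse-encoding practice at desk scale.
    """

    sparsity: int = 20
    tol: float = 1e-6
    max_iter: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sparsity < 1:
            raise ValueError("sparsity must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


# ---------------------------------------------------------------------------
# PCA


def pca_fit(F: DesignMatrix | np.ndarray) -> PCAModel:
    """Thin-SVD PCA keeping k = min(m - 1, rank) components.

    With n >> m (the usual regime here) this reduces the features to at most
    m - 1 dimensions while losing nothing on the training samples.
    """
    if not isinstance(F, DesignMatrix):
        F = DesignMatrix(F)
    X = F.X
    m = X.shape[0]
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = scipy.linalg.svd(Xc, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        warnings.warn("all-constant design matrix; PCA keeps zero components")
        return PCAModel(mean, np.zeros((X.shape[1], 0)), np.zeros(0), F.fingerprint)
    rank = int(np.sum(s > RANK_RTOL * s[0]))
    k = min(m - 1, rank)
    return PCAModel(
        mean=mean,
        components=Vt[:k].T.copy(),
        explained_variance=(s[:k] ** 2) / (m - 1),
        fingerprint=F.fingerprint,
    )


def pca_transform(model: PCAModel, F: DesignMatrix | np.ndarray) -> DesignMatrix:
    X = F.X if isinstance(F, DesignMatrix) else np.asarray(F, dtype=float)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature width {X.shape[1]} does not match the fitted width "
            f"{model.mean.shape[0]}"
        )
    Z = (X - model.mean) @ model.components
    ids = F.sample_ids if isinstance(F, DesignMatrix) else None
    return DesignMatrix(Z, ids, model.fingerprint, pca_applied=True)


# ---------------------------------------------------------------------------
# ROMP


def _regularized_subset(u: np.ndarray, K: int) -> np.ndarray:
    """ROMP coordinate selection on a correlation vector.

    Among the K largest-|u| coordinates, return the contiguous (in sorted
    order) subset whose magnitudes are within a factor of two of each other
    and whose energy ||u_J||^2 is maximal.  Ties go to the subset containing
    the largest-magnitude coordinate.
    """
    mag = np.abs(u)
    order = np.argsort(-mag, kind="stable")[:K]
    order = order[mag[order] > 0]
    if order.size == 0:
        return order
    vals = mag[order]
    best_energy, best = -1.0, None
    for a in range(vals.size):
        # window [a, b): all vals in it are <= vals[a] and >= vals[a]/2
        b = int(np.searchsorted(-vals, -(vals[a] / 2.0), side="right"))
        energy = float(np.sum(vals[a:b] ** 2))
        if energy > best_energy + 0.0:
            best_energy, best = energy, (a, b)
    a, b = best
    return order[a:b]


def romp_fit(
    X: np.ndarray, y: np.ndarray, cfg: FitConfig | None = None
) -> SparseLinearModel:
    """Fit one voxel by ROMP on centered data; intercept via the means."""
    cfg = cfg or FitConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m, k = X.shape
    if y.shape[0] != m:
        raise ValueError(f"response length {y.shape[0]} != sample count {m}")
    if cfg.sparsity > k:
        raise ValueError(f"sparsity K={cfg.sparsity} exceeds feature count {k}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    # The least-squares re-solves on the growing support are done against an
    # incrementally grown orthonormal basis Q of the selected columns (modified
    # Gram-Schmidt with one reorthogonalization pass, R kept for the final
    # triangular solve).  Numerically dependent candidates contribute nothing
    # to the fit and are excluded from the support.
    m_ = Xc.shape[0]
    max_support = 2 * cfg.sparsity
    cap = min(max_support + cfg.sparsity, k, m_)
    Qbuf = np.empty((m_, cap))
    Rbuf = np.zeros((cap, cap))
    beta: list[float] = []
    chosen: list[int] = []
    excluded = np.zeros(k, dtype=bool)

    w = np.zeros(k)
    y_norm = float(np.linalg.norm(yc))
    tol_abs = cfg.tol * y_norm
    r = yc.copy()
    residual_norms = [float(np.linalg.norm(r))]
    converged = y_norm == 0.0
    it = 0
    while not converged and it < cfg.max_iter:
        it += 1
        u = Xc.T @ r
        u[excluded] = 0.0
        if chosen:
            u[chosen] = 0.0  # residual is orthogonal to the support
        J = _regularized_subset(u, cfg.sparsity)
        # truncation keeps the support within the algorithm's 2K bound; J is
        # ordered by decreasing magnitude, so the weakest candidates drop
        J = J[: max_support - len(chosen)]
        added = 0
        for j in J:
            if len(chosen) >= cap:
                break
            t = len(chosen)
            Q = Qbuf[:, :t]
            col = Xc[:, j]
            col_norm = np.linalg.norm(col)
            c1 = Q.T @ col
            q = col - Q @ c1
            c2 = Q.T @ q
            q -= Q @ c2
            rho = np.linalg.norm(q)
            if rho <= 1e-12 * max(col_norm, 1e-300):
                excluded[j] = True  # dependent on the current support
                continue
            q /= rho
            Rbuf[:t, t] = c1 + c2
            Rbuf[t, t] = rho
            Qbuf[:, t] = q
            b_t = float(q @ r)
            beta.append(b_t)
            r = r - q * b_t
            chosen.append(int(j))
            added += 1
        residual_norms.append(float(np.linalg.norm(r)))
        if residual_norms[-1] <= tol_abs:
            converged = True
        if len(chosen) >= max_support or added == 0:
            break
    if chosen:
        t = len(chosen)
        w_q = scipy.linalg.solve_triangular(Rbuf[:t, :t], np.asarray(beta))
        w[chosen] = w_q
    support = np.flatnonzero(w)
    b = y_mean - float(x_mean @ w)
    return SparseLinearModel(
        w=w,
        b=b,
        support=support,
        diagnostics={
            "iterations": it,
            "residual_norms": residual_norms,
            "converged": bool(converged or residual_norms[-1] <= tol_abs),
        },
    )


def fit_voxelwise(
    F_train: DesignMatrix | np.ndarray,
    responses_train: np.ndarray,
    cfg: FitConfig | None = None,
) -> list[SparseLinearModel]:
    """Independent ROMP fit per voxel column, order preserved."""
    cfg = cfg or FitConfig()
    X = F_train.X if isinstance(F_train, DesignMatrix) else np.asarray(F_train, dtype=float)
    R = np.asarray(responses_train, dtype=float)
    if R.ndim != 2 or R.shape[0] != X.shape[0]:
        raise ValueError(
            f"responses must be (m, n_voxels) with m={X.shape[0]}, got {R.shape}"
        )
    models = []
    for j in range(R.shape[1]):
        y = R[:, j]
        if np.ptp(y) == 0.0:
            warnings.warn(f"voxel {j} has zero variance; fitting a constant model")
            models.append(
                SparseLinearModel(
                    np.zeros(X.shape[1]), float(y.mean()), np.array([], dtype=int),
                    {"iterations": 0, "residual_norms": [0.0], "converged": True},
                )
            )
            continue
        models.append(romp_fit(X, y, cfg))
        if (j + 1) % 50 == 0 or j + 1 == R.shape[1]:
            logger.info("fitted %d/%d voxels", j + 1, R.shape[1])
    return models


def predict(
    models: list[SparseLinearModel], F_test: DesignMatrix | np.ndarray
) -> np.ndarray:
    """Predicted responses, one column per voxel: column j = X w_j + b_j."""
    X = F_test.X if isinstance(F_test, DesignMatrix) else np.asarray(F_test, dtype=float)
    k = X.shape[1]
    for j, mdl in enumerate(models):
        if mdl.w.shape[0] != k:
            raise ValueError(
                f"model {j} expects {mdl.w.shape[0]} features, design has {k}"
            )
    W = np.stack([mdl.w for mdl in models], axis=1)
    b = np.array([mdl.b for mdl in models])
    return X @ W + b
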