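"""Direct linear discriminant analysis (DLDA) for high-dimensional patterns.

Classical multi-class LDA solves a generalized eigenproblem involving the
inverse of the within-class scatter, which is singular when the number of
trials is small relative to the pattern dimensionality (here O(10^3)
dimensions vs O(10^3) trials).  Direct LDA sidesteps the inversion by
(1) diagonalizing the *between*-class scatter and keeping the kappa-1
eigenvectors with non-zero eigenvalues (the span of the centered class
means), then (2) diagonalizing the *within*-class scatter inside that basis
and rescaling each dimension to unit within-class variance.

The resulting projection maps patterns into a (kappa-1)-dimensional subspace
S where within-class variance is 1 per dimension, so plain Euclidean
distances in S realize the standardized (Mahalanobis) metric.  The fit is
deterministic: identical input yields an identical projection (ties are
avoided by a fixed sign convention: the largest-magnitude loading of each
column is positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

_SCHEMA_VERSION = 1


class DegenerateClassError(ValueError):
    """A class has fewer than 2 exemplars."""


class RankDeficiencyError(ValueError):
    """Between-class scatter has rank < kappa - 1 (colliding class means)."""


@dataclass
class DiscriminantModel:
    """Fitted DLDA subspace.

    Attributes
    ----------
    projection : (n_dim, kappa-1) array
        Maps patterns linearly into the scaled discriminative subspace S.
    back_projection : (n_dim, kappa-1) array
        Right inverse: ``project(back_project(y)) == y``.
    mean : (n_dim,) array
        Training grand mean (kept for reference; the projection itself is
        purely linear, so a zero pattern maps to zero coordinates).
    class_centroids : (kappa, kappa-1) array
        Training-set class centroids in S.
    classes : (kappa,) array
        Ordered class labels.
    scaling : (kappa-1,) array
        Per-dimension factors that enforce unit within-class variance.
    """

    projection: np.ndarray
    back_projection: np.ndarray
    mean: np.ndarray
    class_centroids: np.ndarray
    classes: np.ndarray
    scaling: np.ndarray
    training_meta: dict = field(default_factory=dict)

    @property
    def n_dim(self) -> int:
        return self.projection.shape[0]

    @property
    def n_components(self) -> int:
        return self.projection.shape[1]


def fit_dlda(patterns: np.ndarray, labels: np.ndarray, *,
             rank_tol: float = 1e-10, within_floor: float = 1e-8,
             floor_mode: str = "floor") -> DiscriminantModel:
    """Fit the two-stage direct LDA.

    Between-class scatter is weighted by class sizes n_i and normalized by N,
    matching the size-weighted SSB of the variance decomposition; the
    projected within-class variance uses the same 1/N convention, so that
    training data projected through the model has within-class variance
    exactly 1 per subspace dimension.

    Parameters
    ----------
    rank_tol : relative threshold on between-class eigenvalues (vs largest)
        below which a dimension is considered rank deficient.
    within_floor : relative floor (vs mean within eigenvalue) applied to
        near-zero within-class eigenvalues before inversion.
    floor_mode : "floor" (default) clips small within eigenvalues; "discard"
        drops the corresponding dimensions.
    """
    X = np.asarray(patterns, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("patterns must be a 2-D array")
    N, n_dim = X.shape
    classes, inv, counts = np.unique(y, return_inverse=True, return_counts=True)
    kappa = len(classes)
    if kappa < 2:
        raise ValueError("need at least 2 classes")
    if np.any(counts < 2):
        bad = classes[counts < 2]
        raise DegenerateClassError(f"classes with <2 exemplars: {bad.tolist()}")
    if n_dim < kappa - 1:
        raise ValueError(f"n_dim={n_dim} < kappa-1={kappa - 1}: DLDA infeasible")

    mu = X.mean(axis=0)
    # class means via aggregation
    C = np.zeros((kappa, n_dim))
    np.add.at(C, inv, X)
    C /= counts[:, None]

    # between-class scatter Sb = Mw^T Mw with Mw the size-weighted centered means
    Mw = np.sqrt(counts / N)[:, None] * (C - mu)
    U, s, Vt = np.linalg.svd(Mw, full_matrices=False)
    evals = s ** 2
    # anchor the rank threshold to the total data scale so that a pure
    # roundoff between-scatter (colliding class means) is detected
    total_var = float(np.sum((X - mu) ** 2)) / N
    keep = evals > max(rank_tol * evals[0], 1e-12 * total_var)
    r = int(np.sum(keep))
    if r < kappa - 1:
        # identify colliding class means for the error message
        colliding = []
        for i in range(kappa):
            for j in range(i + 1, kappa):
                if np.allclose(C[i], C[j]):
                    colliding.append((classes[i], classes[j]))
        raise RankDeficiencyError(
            f"between-class scatter rank {r} < kappa-1={kappa - 1}"
            + (f"; colliding class means: {colliding}" if colliding else ""))
    V = Vt[:r].T                      # n_dim x r, orthonormal
    V1 = V / s[:r]                    # whitens Sb: V1' Sb V1 = I

    # within-class scatter in the whitened between basis (1/N convention)
    Z = (X - C[inv]) @ V1             # N x r
    W = (Z.T @ Z) / N
    lw, Q = np.linalg.eigh(W)
    lw = lw[::-1]
    Q = Q[:, ::-1]
    floor = within_floor * float(np.mean(lw))
    floored = lw < floor
    if floor_mode == "discard" and np.any(floored):
        Q = Q[:, ~floored]
        lw = lw[~floored]
        floored = np.zeros_like(lw, dtype=bool)
    else:
        lw = np.maximum(lw, floor)
    scaling = 1.0 / np.sqrt(lw)
    P = V1 @ (Q * scaling)            # n_dim x r': P' Sw P = I

    # fixed sign convention for reproducibility
    signs = np.sign(P[np.argmax(np.abs(P), axis=0), np.arange(P.shape[1])])
    signs[signs == 0] = 1.0
    P *= signs

    B = P @ np.linalg.inv(P.T @ P)    # right inverse for back-projection
    centroids = C @ P
    meta = {"n_per_class": counts, "n_dim": n_dim, "n_train": N,
            "deterministic": True, "n_floored": int(np.sum(floored)),
            "floor_mode": floor_mode}
    return DiscriminantModel(projection=P, back_projection=B, mean=mu,
                             class_centroids=centroids, classes=classes,
                             scaling=scaling, training_meta=meta)


def project(model: DiscriminantModel, patterns: np.ndarray) -> np.ndarray:
    """Project patterns into the scaled discriminative subspace S."""
    X = np.asarray(patterns, dtype=np.float64)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.n_dim:
        raise ValueError(f"pattern dimension {X.shape[1]} != model n_dim {model.n_dim}")
    out = X @ model.projection
    return out[0] if single else out


def back_project(model: DiscriminantModel, coords: np.ndarray) -> np.ndarray:
    """Map subspace coordinates back into pattern space.

    ``project(model, back_project(model, y)) == y`` up to rounding.
    """
    Y = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    if Y.shape[1] != model.n_components:
        raise ValueError("coordinate dimension mismatch")
    out = Y @ model.back_projection.T
    return out[0] if np.asarray(coords).ndim == 1 else out


@dataclass
class VarianceReport:
    """How the discriminative subspace relates to the principal components."""

    frac_subspace: float        # fraction of total variance inside S
    frac_pca: float             # fraction in the first kappa-1 PCs
    overlap: float              # fraction of S-variance within the PC span
    per_dimension: np.ndarray   # variance share of each S dimension


def variance_report(model: DiscriminantModel, patterns: np.ndarray,
                    labels=None) -> VarianceReport:
    """Variance captured by S vs the first kappa-1 principal components.

    All fractions are ratios of sums of squares of the centered data.  The
    subspace is treated as a geometric object (orthonormalized span of the
    projection columns); the per-dimension shares use the individual
    (normalized) projection columns.
    """
    X = np.asarray(patterns, dtype=np.float64)
    Xc = X - X.mean(axis=0)
    total = float(np.sum(Xc ** 2))
    if total == 0:
        raise ValueError("zero-variance data")
    Qs, _ = np.linalg.qr(model.projection)
    proj_S = Xc @ Qs
    ss_S = float(np.sum(proj_S ** 2))
    # principal components via SVD
    k = model.n_components
    _, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    Qp = Vt[:k].T
    ss_P = float(np.sum(sv[:k] ** 2))
    # S-variance that falls inside the PC span
    ss_overlap = float(np.sum(((proj_S @ Qs.T) @ Qp) ** 2))
    cols = model.projection / np.linalg.norm(model.projection, axis=0)
    per_dim = np.sum((Xc @ cols) ** 2, axis=0) / total
    return VarianceReport(frac_subspace=ss_S / total, frac_pca=ss_P / total,
                          overlap=min(1.0, ss_overlap / ss_S if ss_S else 0.0),
                          per_dimension=per_dim)


def save_model(model: DiscriminantModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = _SCHEMA_VERSION
        f.create_dataset("projection", data=model.projection)
        f.create_dataset("back_projection", data=model.back_projection)
        f.create_dataset("mean", data=model.mean)
        f.create_dataset("class_centroids", data=model.class_centroids)
        f.create_dataset("classes", data=np.asarray(model.classes))
        f.create_dataset("scaling", data=model.scaling)
        for k, v in model.training_meta.items():
            f.attrs[f"meta_{k}"] = v


def load_model(path) -> DiscriminantModel:
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema: {f.attrs.get('schema_version')}")
        meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
        return DiscriminantModel(
            projection=f["projection"][()], back_projection=f["back_projection"][()],
            mean=f["mean"][()], class_centroids=f["class_centroids"][()],
            classes=f["classes"][()], scaling=f["scaling"][()], training_meta=meta)
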