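"""Min-max scaling, PCA, linear discriminant analysis, and sample-level LOOCV.

The classifier is the classic chemometric two-stage scheme: features are
scaled to [0, 1], rotated by principal component analysis, and the retained
scores are classified with a Gaussian linear discriminant (shared pooled
within-class covariance).  The two-stage construction guards against the
singular within-class scatter that plain LDA suffers when measurements
outnumber samples per class.

Validation is leave-one-*sample*-out: all replicate measurements of one
physical sample are held out together, so replicates of the same bottle
never appear on both sides of a fold.  By default the scaler and the PCA
rotation are fitted once on the full dataset (mirroring the sequential
exploratory-then-supervised workflow this pipeline reproduces) while the
discriminant is refitted per fold; ``fit_scope="per_fold"`` refits all
three stages inside each fold, which is the leakage-free variant.

Everything here is deterministic; randomness enters only through the
synthetic generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .absorbance import DatasetTable, FEATURE_COLUMNS
from .categories import CATEGORY_ORDER
from .errors import ConfigurationError, DataError

__all__ = [
    "NormalizationParams",
    "PCAModel",
    "LDAModel",
    "PipelineConfig",
    "CVResult",
    "fit_minmax",
    "apply_minmax",
    "fit_pca",
    "pca_transform",
    "fit_lda",
    "lda_predict",
    "lda_discriminants",
    "lda_canonical_scores",
    "loocv_by_sample",
]


# ---------------------------------------------------------------------------
# min-max normalization


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature minimum and maximum learned from training data."""

    minimum: np.ndarray
    maximum: np.ndarray

    @property
    def n_features(self) -> int:
        return self.minimum.shape[0]


def fit_minmax(X: np.ndarray) -> NormalizationParams:
    """Learn per-feature min/max; requires at least two observations."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError(f"min-max fit needs a 2-D matrix with >= 2 rows, got shape {X.shape}")
    return NormalizationParams(minimum=X.min(axis=0), maximum=X.max(axis=0))


def apply_minmax(X: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Scale features to [0, 1] using training min/max (no clipping).

    Constant features (max == min) map to 0 with a warning.  Validation data
    outside the training range legitimately falls outside [0, 1].
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.n_features:
        raise DataError(
            f"feature count mismatch: data has shape {X.shape}, params expect {params.n_features}"
        )
    span = params.maximum - params.minimum
    constant = span == 0
    if constant.any():
        warnings.warn(
            f"constant feature column(s) {np.flatnonzero(constant).tolist()} mapped to 0",
            stacklevel=2,
        )
    safe = np.where(constant, 1.0, span)
    out = (X - params.minimum) / safe
    out[:, constant] = 0.0
    return out


# ---------------------------------------------------------------------------
# PCA


@dataclass(frozen=True)
class PCAModel:
    """Mean vector, orthonormal loadings, eigenvalues and variance ratios."""

    mean: np.ndarray
    loadings: np.ndarray          # (n_features, k), orthonormal columns
    eigenvalues: np.ndarray       # (k,), non-increasing
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def fit_pca(X: np.ndarray, k: int) -> PCAModel:
    """Principal component analysis of the sample covariance via SVD.

    The sign of each loading column is fixed so that its largest-magnitude
    element is positive, making the decomposition reproducible.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataError("PCA input must be a 2-D matrix")
    n, d = X.shape
    if not 1 <= k <= min(n - 1, d):
        raise ConfigurationError(
            f"k={k} invalid: must satisfy 1 <= k <= min(n-1, d) = {min(n - 1, d)}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s ** 2 / (n - 1)
    total_var = eigenvalues.sum()
    loadings = Vt[:k].T.copy()
    for j in range(k):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    ratios = eigenvalues[:k] / total_var if total_var > 0 else np.zeros(k)
    return PCAModel(mean=mean, loadings=loadings,
                    eigenvalues=eigenvalues[:k], explained_variance_ratio=ratios)


def pca_transform(X: np.ndarray, model: PCAModel) -> np.ndarray:
    """Project observations onto the retained components (scores)."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.mean.shape[0]:
        raise DataError(
            f"feature count mismatch: data has {X.shape[-1]}, model expects {model.mean.shape[0]}"
        )
    return (X - model.mean) @ model.loadings


# ---------------------------------------------------------------------------
# LDA


@dataclass(frozen=True)
class LDAModel:
    """Gaussian linear discriminant with pooled within-class covariance."""

    classes: tuple[str, ...]
    means: np.ndarray          # (n_classes, d)
    covariance: np.ndarray     # (d, d) pooled within-class, SPD after regularization
    priors: np.ndarray         # (n_classes,), > 0, sums to 1
    regularized: bool = False


def _class_order(labels: np.ndarray) -> tuple[str, ...]:
    present = list(dict.fromkeys(labels.tolist()))
    if set(present) <= set(CATEGORY_ORDER):
        return tuple(c for c in CATEGORY_ORDER if c in present)
    return tuple(present)


def fit_lda(scores: np.ndarray, labels: Sequence[str], priors=None,
            *, ridge_scale: float = 1e-8) -> LDAModel:
    """Fit class means and pooled within-class covariance in score space.

    ``priors`` may be ``None``/``"equal"`` (default: equal across classes),
    ``"proportional"`` (class frequencies), or an explicit array in class
    order.  If the pooled covariance is numerically singular a ridge
    ``lambda * I`` with ``lambda = ridge_scale * trace / d`` is added (warned).
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DataError("scores and labels must align")
    classes = _class_order(y)
    if len(classes) < 2:
        raise DataError("LDA needs at least two classes")
    n, d = X.shape
    means = np.empty((len(classes), d))
    pooled = np.zeros((d, d))
    counts = np.empty(len(classes))
    for i, cls in enumerate(classes):
        Xi = X[y == cls]
        if Xi.shape[0] < 2:
            raise DataError(f"class {cls!r} has fewer than 2 observations")
        counts[i] = Xi.shape[0]
        means[i] = Xi.mean(axis=0)
        centered = Xi - means[i]
        pooled += centered.T @ centered
    pooled /= n - len(classes)
    pooled = (pooled + pooled.T) / 2.0

    regularized = False
    smallest = np.linalg.eigvalsh(pooled)[0]
    # relative threshold: eigenvalues this far below the mean variance make
    # the discriminant solve numerically singular
    if smallest <= 1e-12 * np.trace(pooled) / d or not np.isfinite(smallest):
        lam = ridge_scale * np.trace(pooled) / d
        if lam <= 0:
            lam = ridge_scale
        warnings.warn(
            f"pooled covariance singular (min eigenvalue {smallest:.3g}); "
            f"ridge {lam:.3g} * I applied",
            stacklevel=2,
        )
        pooled = pooled + lam * np.eye(d)
        regularized = True

    if priors is None or (isinstance(priors, str) and priors == "equal"):
        pri = np.full(len(classes), 1.0 / len(classes))
    elif isinstance(priors, str) and priors == "proportional":
        pri = counts / n
    else:
        pri = np.asarray(priors, dtype=float)
        if pri.shape != (len(classes),) or (pri <= 0).any():
            raise ConfigurationError("explicit priors must be positive, one per class")
        pri = pri / pri.sum()
    return LDAModel(classes=classes, means=means, covariance=pooled,
                    priors=pri, regularized=regularized)


def lda_discriminants(X: np.ndarray, model: LDAModel) -> np.ndarray:
    """Linear discriminant value per class:
    ``delta_k(x) = x' Sigma^-1 mu_k - 1/2 mu_k' Sigma^-1 mu_k + ln pi_k``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.means.shape[1]:
        raise DataError(
            f"feature count mismatch: data has {X.shape[1]}, model expects {model.means.shape[1]}"
        )
    W = np.linalg.solve(model.covariance, model.means.T)       # (d, K)
    const = -0.5 * np.einsum("kd,dk->k", model.means, W) + np.log(model.priors)
    return X @ W + const


def lda_predict(X: np.ndarray, model: LDAModel) -> np.ndarray:
    """Predicted class per observation; ties break toward the earlier class
    in the fixed label order (Silver < Aged < Extra-aged)."""
    delta = lda_discriminants(X, model)
    idx = np.argmax(delta, axis=1)  # argmax returns the first maximum: tie-break by order
    return np.asarray(model.classes, dtype=object)[idx]


def lda_canonical_scores(X: np.ndarray, model: LDAModel, n_components: int = 2) -> np.ndarray:
    """Canonical discriminant coordinates (for score plots).

    Solves the generalized eigenproblem of between-class vs within-class
    scatter via Cholesky whitening and returns the top ``n_components``
    projections of ``X``.
    """
    X = np.asarray(X, dtype=float)
    grand = model.means.mean(axis=0)
    diff = model.means - grand
    Sb = diff.T @ diff
    L = np.linalg.cholesky(model.covariance)
    Linv = np.linalg.inv(L)
    M = Linv @ Sb @ Linv.T
    M = (M + M.T) / 2.0
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1][:n_components]
    A = Linv.T @ evecs[:, order]
    return (X - grand) @ A


# ---------------------------------------------------------------------------
# LOOCV pipeline


@dataclass
class PipelineConfig:
    """Settings of the normalization -> PCA -> LDA pipeline.

    ``unit`` chooses the observation row: every image replicate
    (``"replicate"``, 750 rows by default) or per-cuvette averages
    (``"cuvette"``, 75 rows).  ``fit_scope`` chooses whether normalization
    and PCA are fitted once globally (default) or inside each fold.
    """

    features: tuple[str, ...] = FEATURE_COLUMNS
    unit: str = "replicate"
    n_components: int = 3
    priors: str = "equal"
    fit_scope: str = "global"
    ridge_scale: float = 1e-8

    def __post_init__(self) -> None:
        if self.unit not in ("replicate", "cuvette"):
            raise ConfigurationError(f"unit must be 'replicate' or 'cuvette', got {self.unit!r}")
        if self.fit_scope not in ("global", "per_fold"):
            raise ConfigurationError(
                f"fit_scope must be 'global' or 'per_fold', got {self.fit_scope!r}"
            )
        if self.priors not in ("equal", "proportional"):
            raise ConfigurationError(f"priors must be 'equal' or 'proportional', got {self.priors!r}")
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")

    def to_dict(self) -> dict:
        return {
            "features": list(self.features), "unit": self.unit,
            "n_components": self.n_components, "priors": self.priors,
            "fit_scope": self.fit_scope, "ridge_scale": self.ridge_scale,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "features" in data:
            data["features"] = tuple(data["features"])
        return cls(**data)


@dataclass
class CVResult:
    """Per-replicate predictions of a sample-level leave-one-out run.

    ``frame`` columns: fold, tag, true, predicted, cuvette, image.
    """

    frame: pd.DataFrame
    n_folds: int
    explained_variance_ratio: np.ndarray | None = None

    def __post_init__(self) -> None:
        tags = self.frame.groupby("tag")["fold"].nunique()
        if (tags != 1).any():
            raise DataError("each tag must be validated in exactly one fold")
        if self.frame["fold"].nunique() != self.n_folds:
            raise DataError("fold count does not match the number of samples")


def _observation_frame(dataset: DatasetTable, config: PipelineConfig) -> pd.DataFrame:
    frame = dataset.frame
    missing = [c for c in config.features if c not in frame.columns]
    if missing:
        raise DataError(f"dataset lacks feature column(s) {missing}")
    if config.unit == "cuvette":
        grouped = (
            frame.groupby(["tag", "category", "cuvette"], sort=False)[list(config.features)]
            .mean().reset_index()
        )
        grouped["image"] = 0
        return grouped
    return frame.copy()


def loocv_folds(tags: Sequence[str]) -> list[tuple[int, str]]:
    """Enumerate leave-one-sample-out folds: one fold per unique tag, in order."""
    unique = list(dict.fromkeys(tags))
    if len(unique) < 2:
        raise DataError("LOOCV needs at least two samples")
    return list(enumerate(unique))


def loocv_by_sample(dataset: DatasetTable, config: PipelineConfig | None = None) -> CVResult:
    """Leave-one-sample-out cross-validation of the two-stage classifier.

    Each fold holds out every replicate of one sample; the discriminant is
    refitted on the remaining samples and applied to the held-out
    replicates.  With the default ``fit_scope="global"`` the scaler and PCA
    rotation are fitted once on all observations before folding.
    """
    config = config or PipelineConfig()
    dataset.require_classifiable()
    obs = _observation_frame(dataset, config)
    tags = list(dict.fromkeys(obs["tag"]))
    if len(tags) < 2:
        raise DataError("LOOCV needs at least two samples")

    tag_cat = obs.drop_duplicates("tag").set_index("tag")["category"]
    counts = tag_cat.value_counts()
    X = obs[list(config.features)].to_numpy(dtype=float)
    y = obs["category"].to_numpy()

    evr = None
    if config.fit_scope == "global":
        norm = fit_minmax(X)
        Xn = apply_minmax(X, norm)
        pca = fit_pca(Xn, config.n_components)
        scores_all = pca_transform(Xn, pca)
        evr = pca.explained_variance_ratio

    records = []
    for fold, tag in enumerate(tags):
        held_cat = tag_cat[tag]
        remaining = counts[held_cat] - 1
        if remaining < 2 or (counts.drop(held_cat) < 2).any():
            raise DataError(
                f"fold {fold} (held-out {tag}): a category would have < 2 training samples"
            )
        test_mask = (obs["tag"] == tag).to_numpy()
        train_mask = ~test_mask
        if config.fit_scope == "global":
            train_scores, test_scores = scores_all[train_mask], scores_all[test_mask]
        else:
            norm = fit_minmax(X[train_mask])
            pca = fit_pca(apply_minmax(X[train_mask], norm), config.n_components)
            train_scores = pca_transform(apply_minmax(X[train_mask], norm), pca)
            test_scores = pca_transform(apply_minmax(X[test_mask], norm), pca)
        lda = fit_lda(train_scores, y[train_mask], priors=config.priors,
                      ridge_scale=config.ridge_scale)
        predicted = lda_predict(test_scores, lda)
        sub = obs[test_mask]
        for (_, row), pred in zip(sub.iterrows(), predicted):
            records.append((fold, tag, held_cat, pred, int(row["cuvette"]), int(row["image"])))

    frame = pd.DataFrame(records, columns=["fold", "tag", "true", "predicted", "cuvette", "image"])
    return CVResult(frame=frame, n_folds=len(tags), explained_variance_ratio=evr)
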