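"""Normalization, PCA, LDA and sample-level LOOCV against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from eeye.chemometrics import (
    PipelineConfig,
    apply_minmax,
    fit_lda,
    fit_minmax,
    fit_pca,
    lda_canonical_scores,
    lda_discriminants,
    lda_predict,
    loocv_by_sample,
    loocv_folds,
    pca_transform,
)
from eeye.errors import ConfigurationError, DataError
from eeye.synthetic import generate_feature_dataset

# ---------------------------------------------------------------------------
# min-max


def test_minmax_midpoint_and_extremes():
    X = np.array([[0.04], [0.12], [0.08]])
    params = fit_minmax(X)
    out = apply_minmax(X, params)
    assert out[:, 0] == pytest.approx([0.0, 1.0, 0.5])


def test_minmax_constant_column_maps_to_zero_with_warning():
    X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
    params = fit_minmax(X)
    with pytest.warns(UserWarning, match="constant"):
        out = apply_minmax(X, params)
    assert (out[:, 1] == 0.0).all()
    assert out[:, 0] == pytest.approx([0.0, 0.5, 1.0])


def test_minmax_validation_data_may_leave_unit_interval():
    params = fit_minmax(np.array([[0.0], [1.0]]))
    out = apply_minmax(np.array([[2.0], [-1.0]]), params)
    assert out[:, 0] == pytest.approx([2.0, -1.0])


def test_minmax_feature_mismatch_rejected():
    params = fit_minmax(np.zeros((3, 2)) + np.arange(3)[:, None])
    with pytest.raises(DataError):
        apply_minmax(np.zeros((3, 3)), params)


# ---------------------------------------------------------------------------
# PCA


def test_collinear_points_need_one_component(rng):
    t = rng.normal(size=20)
    X = np.outer(t, [1.0, 2.0, -1.0])
    model = fit_pca(X, 1)
    assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_matches_eigendecomposition_oracle(rng):
    """Scores and eigenvalues agree (up to sign) with a covariance
    eigendecomposition computed independently of the SVD code path."""
    for _ in range(100):
        n, d = int(rng.integers(5, 15)), int(rng.integers(2, 5))
        k = min(n - 1, d)
        X = rng.normal(size=(n, d))
        model = fit_pca(X, k)
        C = np.cov(X.T, ddof=1).reshape(d, d)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1][:k]
        assert np.allclose(model.eigenvalues, evals[order], atol=1e-8)
        scores = pca_transform(X, model)
        oracle_scores = (X - X.mean(axis=0)) @ evecs[:, order]
        assert np.allclose(np.abs(scores), np.abs(oracle_scores), atol=1e-8)


def test_pca_matches_sklearn(rng):
    sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
    X = rng.normal(size=(30, 3))
    model = fit_pca(X, 3)
    sk = sklearn_pca(n_components=3).fit(X)
    assert np.allclose(model.eigenvalues, sk.explained_variance_, atol=1e-10)
    assert np.allclose(np.abs(model.loadings), np.abs(sk.components_.T), atol=1e-10)


def test_full_rank_reconstruction(rng):
    X = rng.normal(size=(10, 3))
    model = fit_pca(X, 3)
    scores = pca_transform(X, model)
    assert np.allclose(scores @ model.loadings.T + model.mean, X, atol=1e-8)


def test_pca_invariants(rng):
    X = rng.normal(size=(12, 4))
    model = fit_pca(X, 3)
    # orthonormal loadings
    assert np.allclose(model.loadings.T @ model.loadings, np.eye(3), atol=1e-8)
    # mean maps to the origin
    assert np.allclose(pca_transform(X.mean(axis=0)[None, :], model), 0.0, atol=1e-10)
    # score variance equals retained eigenvalues
    scores = pca_transform(X, model)
    assert np.allclose(scores.var(axis=0, ddof=1), model.eigenvalues, atol=1e-8)
    # ratios non-increasing and bounded
    evr = model.explained_variance_ratio
    assert (np.diff(evr) <= 1e-12).all() and evr.sum() <= 1 + 1e-12
    # deterministic sign convention: largest-magnitude element positive
    for j in range(model.loadings.shape[1]):
        col = model.loadings[:, j]
        assert col[np.argmax(np.abs(col))] > 0


def test_pca_k_too_large_rejected(rng):
    with pytest.raises(ConfigurationError):
        fit_pca(rng.normal(size=(5, 3)), 5)


# ---------------------------------------------------------------------------
# LDA


def _brute_force_predict(X, model):
    """Direct evaluation of the Gaussian linear discriminant per class."""
    inv = np.linalg.inv(model.covariance)
    preds = []
    for x in X:
        best_val, best_cls = -np.inf, None
        for mu, pi, cls in zip(model.means, model.priors, model.classes):
            delta = x @ inv @ mu - 0.5 * mu @ inv @ mu + np.log(pi)
            if delta > best_val:
                best_val, best_cls = delta, cls
        preds.append(best_cls)
    return np.array(preds, dtype=object)


def test_separated_clouds_classified_perfectly(rng):
    X = np.vstack([rng.normal(0, 0.3, size=(20, 2)), rng.normal(5, 0.3, size=(20, 2))])
    y = np.array(["Silver"] * 20 + ["Aged"] * 20)
    model = fit_lda(X, y)
    assert (lda_predict(X, model) == y).all()


def test_tie_breaks_toward_earlier_class_in_order():
    # symmetric clouds around the origin; the origin is Mahalanobis-equidistant
    X = np.array([[-2.0, 0.0], [-2.0, 1.0], [-2.0, -1.0],
                  [2.0, 0.0], [2.0, 1.0], [2.0, -1.0]])
    y = np.array(["Aged", "Aged", "Aged", "Silver", "Silver", "Silver"])
    model = fit_lda(X, y, priors="equal")
    assert model.classes == ("Silver", "Aged")  # fixed category order
    assert lda_predict(np.array([[0.0, 0.0]]), model)[0] == "Silver"


def test_lda_matches_brute_force_discriminant(rng):
    for _ in range(100):
        d = int(rng.integers(1, 4))
        centers = rng.normal(scale=3.0, size=(3, d))
        sizes = [int(rng.integers(3, 8)) for _ in range(3)]
        X = np.vstack([rng.normal(c, 1.0, size=(s, d)) for c, s in zip(centers, sizes)])
        y = np.array(sum([[cls] * s for cls, s in
                          zip(("Silver", "Aged", "Extra-aged"), sizes)], []), dtype=object)
        model = fit_lda(X, y, priors=rng.choice(["equal", "proportional"]))
        queries = rng.normal(scale=3.0, size=(10, d))
        assert (lda_predict(queries, model) == _brute_force_predict(queries, model)).all()


def test_lda_matches_sklearn(rng):
    lda_cls = pytest.importorskip("sklearn.discriminant_analysis").LinearDiscriminantAnalysis
    X = np.vstack([rng.normal(c, 1.0, size=(15, 3)) for c in ([0, 0, 0], [3, 1, 0], [0, 3, 3])])
    y = np.array(["Silver"] * 15 + ["Aged"] * 15 + ["Extra-aged"] * 15)
    model = fit_lda(X, y, priors="equal")
    sk = lda_cls(priors=[1 / 3] * 3).fit(X, y)
    queries = rng.normal(scale=2.0, size=(50, 3))
    assert (lda_predict(queries, model) == sk.predict(queries)).all()


def test_lda_affine_invariance(rng):
    X = np.vstack([rng.normal(c, 1.0, size=(10, 2)) for c in ([0, 0], [4, 0], [0, 4])])
    y = np.array(["Silver"] * 10 + ["Aged"] * 10 + ["Extra-aged"] * 10)
    A = np.array([[2.0, 0.5], [-0.3, 1.5]])
    b = np.array([1.0, -2.0])
    queries = rng.normal(scale=2.0, size=(20, 2))
    base = lda_predict(queries, fit_lda(X, y))
    mapped = lda_predict(queries @ A.T + b, fit_lda(X @ A.T + b, y))
    assert (base == mapped).all()


def test_lda_small_class_rejected():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 5.0]])
    y = np.array(["Silver", "Silver", "Aged"])
    with pytest.raises(DataError, match="Aged"):
        fit_lda(X, y)


def test_singular_covariance_regularized_with_warning(rng):
    # all within-class variation along one axis -> singular 2-D covariance
    X = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0],
                  [10.0, 5.0], [11.0, 5.0], [12.0, 5.0]])
    y = np.array(["Silver"] * 3 + ["Aged"] * 3)
    with pytest.warns(UserWarning, match="ridge"):
        model = fit_lda(X, y)
    assert model.regularized
    assert np.linalg.eigvalsh(model.covariance)[0] > 0
    # still classifies the training data
    assert (lda_predict(X, model) == y).all()


def test_canonical_scores_shape(rng):
    X = np.vstack([rng.normal(c, 1.0, size=(10, 3)) for c in ([0, 0, 0], [4, 0, 0], [0, 4, 0])])
    y = np.array(["Silver"] * 10 + ["Aged"] * 10 + ["Extra-aged"] * 10)
    scores = lda_canonical_scores(X, fit_lda(X, y), n_components=2)
    assert scores.shape == (30, 2)


def test_discriminant_feature_mismatch(rng):
    X = rng.normal(size=(8, 2))
    y = np.array(["Silver"] * 4 + ["Aged"] * 4)
    model = fit_lda(X, y)
    with pytest.raises(DataError):
        lda_discriminants(rng.normal(size=(3, 5)), model)


# ---------------------------------------------------------------------------
# LOOCV


def test_loocv_partitions_dataset(noisy_toy_config):
    ds = generate_feature_dataset(noisy_toy_config)
    cv = loocv_by_sample(ds)
    assert cv.n_folds == 9
    # every tag validated exactly once, every replicate exactly once
    assert cv.frame.groupby("tag")["fold"].nunique().eq(1).all()
    assert len(cv.frame) == len(ds.frame)
    key = ["tag", "cuvette", "image"]
    assert (cv.frame[key].sort_values(key).reset_index(drop=True)
            == ds.frame[key].sort_values(key).reset_index(drop=True)).all().all()


def test_loocv_fold_enumeration_minimal():
    assert loocv_folds(["S1", "A1"]) == [(0, "S1"), (1, "A1")]
    assert loocv_folds(["S1", "S1", "A1"]) == [(0, "S1"), (1, "A1")]
    with pytest.raises(DataError):
        loocv_folds(["S1"])


def test_separable_dataset_classified_perfectly(separable_config):
    ds = generate_feature_dataset(separable_config)
    cv = loocv_by_sample(ds)
    assert (cv.frame["true"] == cv.frame["predicted"]).all()


def test_per_fold_scope_also_recovers_separable(separable_config):
    ds = generate_feature_dataset(separable_config)
    cv = loocv_by_sample(ds, PipelineConfig(fit_scope="per_fold"))
    assert (cv.frame["true"] == cv.frame["predicted"]).all()


def test_cuvette_unit_reduces_observations(separable_config):
    ds = generate_feature_dataset(separable_config)
    cv = loocv_by_sample(ds, PipelineConfig(unit="cuvette"))
    # 9 samples x 2 cuvettes
    assert len(cv.frame) == 18


def test_vanishing_category_error_names_fold(separable_config):
    ds = generate_feature_dataset(separable_config)
    frame = ds.frame[~ds.frame["tag"].isin(["EA3"])].copy()  # EA down to 2 samples
    ds2 = type(ds)(frame)
    with pytest.raises(DataError, match="fold"):
        loocv_by_sample(ds2)


def test_explained_variance_reported_in_global_scope(separable_config):
    ds = generate_feature_dataset(separable_config)
    cv = loocv_by_sample(ds)
    assert cv.explained_variance_ratio is not None
    assert cv.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
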