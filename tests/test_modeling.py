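"""PCA, the classifier bank, cross-validation and metrics."""

import numpy as np
import pytest
from sklearn.datasets import make_moons

from calyxscan import (cross_validate, evaluate, f1_from_precision_recall,
                       fit_pca, train_classifier, transform_pca)
from calyxscan.errors import (AlignmentError, DegenerateLabelError,
                              ParameterError)
from calyxscan.modeling import CLASSIFIER_TAGS, report_from_predictions


def _two_gaussians(rng, n=60, sep=6.0, d=4):
    x = np.vstack([rng.normal(0, 1, size=(n, d)),
                   rng.normal(sep, 1, size=(n, d))])
    y = np.array(["healthy"] * n + ["infested"] * n, dtype=object)
    return x, y


class TestPca:
    def test_rank_one_data(self, rng):
        direction = rng.normal(size=5)
        x = rng.normal(size=(30, 1)) * direction
        model = fit_pca(x, 0.5)
        assert model.loadings.shape[1] == 1
        np.testing.assert_allclose(model.explained_variance_ratio[0], 1.0,
                                   atol=1e-12)

    def test_isotropic_two_ratios_half(self, rng):
        x = rng.normal(size=(4000, 2))
        model = fit_pca(x, 2)
        np.testing.assert_allclose(model.explained_variance_ratio,
                                   [0.5, 0.5], atol=0.05)

    def test_eigenvalues_match_covariance_eig_oracle(self, rng):
        """SVD route agrees with an independent covariance eigendecomposition."""
        x = rng.normal(size=(20, 5))
        model = fit_pca(x, 5)
        cov = np.cov(x, rowvar=False, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(model.explained_variance, eigvals,
                                   atol=1e-8)
        # loadings orthonormal, ratios non-increasing and in [0, 1]
        np.testing.assert_allclose(model.loadings.T @ model.loadings,
                                   np.eye(5), atol=1e-10)
        r = model.explained_variance_ratio
        assert np.all(np.diff(r) <= 1e-12) and r.sum() <= 1 + 1e-12

    def test_sign_convention(self, rng):
        x = rng.normal(size=(25, 6))
        model = fit_pca(x, 4)
        for j in range(4):
            col = model.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_transform_properties(self, rng):
        x = rng.normal(size=(40, 6))
        model = fit_pca(x, 3)
        np.testing.assert_allclose(transform_pca(model, model.mean), 0.0,
                                   atol=1e-10)
        scores = transform_pca(model, x)
        recon = model.mean + scores @ model.loadings.T
        assert np.all(
            np.linalg.norm(x - recon, axis=1)
            <= np.linalg.norm(x - model.mean, axis=1) + 1e-10)
        cov = np.cov(scores, rowvar=False, ddof=1)
        np.testing.assert_allclose(np.diag(cov), model.explained_variance,
                                   atol=1e-8)

    def test_errors(self, rng):
        x = rng.normal(size=(10, 4))
        with pytest.raises(ParameterError):
            fit_pca(x, 5)
        model = fit_pca(x, 2)
        with pytest.raises(AlignmentError):
            transform_pca(model, rng.normal(size=(3, 7)))


class TestClassifierBank:
    @pytest.mark.parametrize("tag", CLASSIFIER_TAGS)
    def test_separable_clusters_fit_perfectly(self, rng, tag):
        x, y = _two_gaussians(rng)
        model = train_classifier(tag, x, y, seed=0)
        assert evaluate(model, x, y).accuracy == 1.0

    def test_knn_one_neighbour_memorizes(self, rng):
        x, y = _two_gaussians(rng, sep=0.5)
        model = train_classifier("knn", x, y, {"n_neighbors": 1})
        assert evaluate(model, x, y).accuracy == 1.0

    def test_permuted_labels_score_at_chance(self, rng):
        x, y = _two_gaussians(rng, n=200, sep=4.0)
        y_perm = rng.permutation(y)
        cv = cross_validate("lda", x, y_perm, folds=5, seed=1)
        half = 2.5758 * 0.5 / np.sqrt(len(y_perm))
        assert abs(cv["mean_accuracy"] - 0.5) <= 3 * half

    def test_nonlinear_boundary_favours_trees_over_lda(self):
        x, y_num = make_moons(n_samples=400, noise=0.15, random_state=3)
        y = np.where(y_num == 1, "infested", "healthy").astype(object)
        gtb = cross_validate("gtb", x, y, folds=5, seed=0,
                             hyperparams={"n_estimators": 100})
        lda = cross_validate("lda", x, y, folds=5, seed=0)
        assert gtb["mean_accuracy"] > lda["mean_accuracy"]

    def test_errors(self, rng):
        x, y = _two_gaussians(rng)
        with pytest.raises(ParameterError):
            train_classifier("mlp", x, y)
        with pytest.raises(DegenerateLabelError):
            train_classifier("lda", x, np.array(["healthy"] * len(x)))


class TestMetrics:
    def test_f1_equals_precision_when_balanced(self):
        assert f1_from_precision_recall(0.8, 0.8) == pytest.approx(0.8)
        assert f1_from_precision_recall(0.0, 0.0) == 0.0

    def test_hand_counted_confusion(self):
        """TP=9, FP=1, FN=3, TN=7 → P=0.9, R=0.75, F1=0.8182, acc=0.8."""
        y = np.array(["infested"] * 12 + ["healthy"] * 8, dtype=object)
        pred = np.array(["infested"] * 9 + ["healthy"] * 3
                        + ["infested"] * 1 + ["healthy"] * 7, dtype=object)
        rep = report_from_predictions(y, pred)
        inf = rep.per_class["infested"]
        assert inf["precision"] == pytest.approx(0.9)
        assert inf["recall"] == pytest.approx(0.75)
        assert inf["f1"] == pytest.approx(2 * 0.9 * 0.75 / 1.65, abs=1e-12)
        assert rep.accuracy == pytest.approx(0.8)

    def test_accuracy_consistent_with_confusion(self, rng):
        x, y = _two_gaussians(rng, sep=1.5)
        model = train_classifier("knn", x, y)
        rep = evaluate(model, x, y)
        pred = model.predict(x)
        tp = ((pred == "infested") & (y == "infested")).sum()
        tn = ((pred == "healthy") & (y == "healthy")).sum()
        assert rep.accuracy == pytest.approx((tp + tn) / len(y), abs=1e-12)


class TestCrossValidate:
    def test_separable_data_perfect_with_zero_sd(self, rng):
        x, y = _two_gaussians(rng, n=50)
        cv = cross_validate("lda", x, y, folds=5, seed=0)
        assert cv["mean_accuracy"] == 1.0 and cv["sd_accuracy"] == 0.0

    def test_fold_bookkeeping(self, rng):
        x, y = _two_gaussians(rng, n=26)
        cv = cross_validate("knn", x, y, folds=5, seed=0)
        sizes = [r.n_observations for r in cv["fold_reports"]]
        assert sum(sizes) == 52 and max(sizes) - min(sizes) <= 1

    def test_matches_manual_fold_loop(self, rng):
        """Mean CV accuracy equals an explicit loop over the same folds."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.model_selection import StratifiedKFold

        x, y = _two_gaussians(rng, n=40, sep=1.0)
        cv = cross_validate("lda", x, y, folds=5, seed=9)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=9)
        accs = []
        for tr, te in skf.split(x, y):
            m = LinearDiscriminantAnalysis().fit(x[tr], y[tr])
            accs.append(np.mean(m.predict(x[te]) == y[te]))
        assert cv["mean_accuracy"] == pytest.approx(np.mean(accs), abs=1e-12)

    def test_too_few_samples(self, rng):
        x, y = _two_gaussians(rng, n=2)
        with pytest.raises(ParameterError):
            cross_validate("lda", x[:4], y[:4], folds=5)
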