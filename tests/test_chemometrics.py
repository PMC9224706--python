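"""PCA, Fisher LDA, LD1 shape scores and leave-one-out cross-validation."""

import numpy as np
import pytest

from evir.chemometrics import (
    fisher_criterion,
    fit_lda,
    fit_pca,
    loocv_classify,
    pca_lda_scores,
)
from evir.preprocess import CANONICAL_BANDS
from evir.spectra_io import SpectralDataset
from evir import synthetic_data as sd

from conftest import make_spectrum


class TestPca:
    def test_collinear_points_give_single_component(self):
        t = np.linspace(-1, 1, 10)
        X = np.column_stack([t, 2 * t])  # exactly on a line
        model = fit_pca(X, 2)
        total = model.eigenvalues.sum()
        assert model.eigenvalues[0] / total == pytest.approx(1.0, abs=1e-12)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 6))
        model = fit_pca(X, 4)
        np.testing.assert_allclose(
            model.loadings @ model.loadings.T, np.eye(4), atol=1e-10
        )

    def test_eigenpairs_match_covariance_eigendecomposition(self):
        """Eigenvalues/vectors agree with an explicitly formed sample
        covariance decomposed by an independent eigensolver."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 4))
        model = fit_pca(X, 4)
        cov = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(model.eigenvalues, evals, atol=1e-10)
        for i in range(4):
            # eigenvectors defined up to sign
            assert abs(model.loadings[i] @ evecs[:, i]) == pytest.approx(1.0, abs=1e-8)

    def test_scores_centered_with_variance_equal_to_eigenvalues(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 8))
        model = fit_pca(X, 3)
        scores = model.transform(X)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(
            scores.var(axis=0, ddof=1), model.eigenvalues, atol=1e-10
        )

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((3, 5)), 3)  # limit is min(n−1, p) = 2


class TestLda:
    def test_isotropic_clusters_recover_axis_direction(self):
        rng = np.random.default_rng(2)
        X0 = rng.normal(0, 0.1, size=(50, 2))
        X1 = rng.normal(0, 0.1, size=(50, 2)) + np.array([4.0, 0.0])
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        model = fit_lda(X, y)
        # near-perfect alignment up to finite-sample scatter anisotropy
        assert abs(model.direction @ np.array([1.0, 0.0])) > 0.98
        assert model.mean_case > model.mean_control  # sign convention

    def test_direction_matches_closed_form(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3)) @ np.diag([1.0, 2.0, 0.5])
        y = (rng.random(30) < 0.5).astype(int)
        X[y == 1] += np.array([1.0, -0.5, 0.3])
        model = fit_lda(X, y)
        mu0, mu1 = X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)
        sw = sum(
            (X[y == c] - mu).T @ (X[y == c] - mu) for c, mu in ((0, mu0), (1, mu1))
        )
        w = np.linalg.solve(sw, mu1 - mu0)
        w /= np.linalg.norm(w)
        if (X[y == 1] @ w).mean() < (X[y == 0] @ w).mean():
            w = -w
        np.testing.assert_allclose(model.direction, w, atol=1e-8)
        # the closed form is the Fisher-criterion maximizer
        assert fisher_criterion(X, y, model.direction) == pytest.approx(
            fisher_criterion(X, y, w), abs=1e-8
        )

    def test_fitted_direction_beats_random_directions(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        y = (rng.random(40) < 0.5).astype(int)
        X[y == 1, 0] += 2.0
        model = fit_lda(X, y)
        j_fit = fisher_criterion(X, y, model.direction)
        for _ in range(1000):
            w = rng.normal(size=3)
            assert j_fit >= fisher_criterion(X, y, w / np.linalg.norm(w)) - 1e-12

    def test_identical_class_means_rejected(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="no separation"):
            fit_lda(X, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            fit_lda(np.zeros((4, 2)), np.zeros(4, dtype=int))


class TestLd1Scores:
    def test_planted_shape_shift_separates_groups(self, planted_cohort):
        scores = pca_lda_scores(planted_cohort, CANONICAL_BANDS["amide"])
        labels = planted_cohort.labels
        assert scores[labels == 1].mean() > scores[labels == 0].mean()
        assert scores[labels == 1].mean() - scores[labels == 0].mean() > 0.5

    def test_scores_standardized(self, planted_cohort):
        scores = pca_lda_scores(planted_cohort, CANONICAL_BANDS["ester_co"])
        assert scores.mean() == pytest.approx(0.0, abs=1e-10)
        assert scores.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_subject_permutation_equivariance(self, planted_cohort):
        scores = pca_lda_scores(planted_cohort, CANONICAL_BANDS["ch_stretch"])
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(planted_cohort))
        permuted = planted_cohort.subset(perm)
        scores_perm = pca_lda_scores(permuted, CANONICAL_BANDS["ch_stretch"])
        np.testing.assert_allclose(scores_perm, scores[perm], atol=1e-8)


class TestLoocv:
    def test_n39_gives_39_folds(self, planted_cohort):
        report = loocv_classify(planted_cohort, CANONICAL_BANDS["amide"])
        assert report.n_folds == 39
        assert report.tp + report.fn == 20  # cases
        assert report.tn + report.fp == 19  # controls

    def test_overwhelming_separation_classified_perfectly(self, instrument_grid):
        # effect size d = 5 between the groups' band shapes
        g = instrument_grid
        rng = np.random.default_rng(8)
        spectra = []
        for i in range(10):
            c = 1650 + rng.normal(0, 1)
            spectra.append(
                make_spectrum(g, np.exp(-0.5 * ((g - c) / 20) ** 2), f"c{i}", "control")
            )
        for i in range(10):
            c = 1665 + rng.normal(0, 1)  # 15 cm⁻¹ shift ≫ 1 cm⁻¹ jitter
            spectra.append(
                make_spectrum(g, np.exp(-0.5 * ((g - c) / 20) ** 2), f"p{i}", "case")
            )
        report = loocv_classify(SpectralDataset(spectra), CANONICAL_BANDS["amide"])
        assert report.accuracy == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(9)
        accs = []
        for rep in range(20):
            spec = sd.null_cohort_spec(seed=1000 + rep, n_control=20, n_case=20)
            ds = sd.generate_cohort(spec)
            accs.append(loocv_classify(ds, CANONICAL_BANDS["amide"]).accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_per_fold_refit_differs_from_leaky_variant_on_outlier(self, instrument_grid):
        """Refitting PCA inside each fold must change the outcome when one
        subject dominates the variance (guards the classic leakage bug)."""
        g = instrument_grid
        rng = np.random.default_rng(9)
        spectra = []
        for i in range(8):
            ab = np.exp(-0.5 * ((g - 1640 - rng.normal(0, 3)) / 20) ** 2)
            ab = ab + rng.normal(0, 0.01, g.size)
            spectra.append(make_spectrum(g, ab, f"c{i}", "control"))
        for i in range(8):
            ab = np.exp(-0.5 * ((g - 1643 - rng.normal(0, 3)) / 20) ** 2)
            ab = ab + rng.normal(0, 0.01, g.size)
            spectra.append(make_spectrum(g, ab, f"p{i}", "case"))
        # extreme outlier: a different band shape entirely, dominating the variance
        outlier = np.exp(-0.5 * ((g - 1500) / 8) ** 2) * 30 + rng.normal(0, 0.01, g.size)
        spectra.append(make_spectrum(g, outlier, "outlier", "control"))
        ds = SpectralDataset(spectra)
        window = CANONICAL_BANDS["amide"]
        honest = loocv_classify(ds, window, refit_pca=True)
        leaky = loocv_classify(ds, window, refit_pca=False)
        assert not np.array_equal(honest.predictions, leaky.predictions)

    def test_small_n_rejected(self, instrument_grid):
        g = instrument_grid
        ds = SpectralDataset(
            [
                make_spectrum(g, np.exp(-((g - 1600) ** 2) / 500), "a", "control"),
                make_spectrum(g, np.exp(-((g - 1610) ** 2) / 500), "b", "case"),
            ]
        )
        with pytest.raises(ValueError):
            loocv_classify(ds, CANONICAL_BANDS["amide"])
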