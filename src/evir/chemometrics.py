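"""PCA-LDA band-shape scoring and leave-one-out cross-validated classification.

A diagnostic band is first reduced by principal component analysis (PCA,
default two components) and a two-class Fisher linear discriminant is then
fit in PC-score space.  The projection of each subject onto the
discriminant direction — the LD1 score — is a scalar "shape" biomarker for
that band.  Classification performance is estimated by leave-one-out
cross-validation in which the *entire* chain (centering, PCA, LDA,
threshold) is refit on each training fold, so no information from the
held-out subject leaks into the model.

Sign convention: LD1 is oriented so the case group has the higher mean
score.  Reported LD1 scores are standardized to zero pooled mean and unit
pooled variance, making scores comparable across bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .preprocess import BandDefinition, preprocess_band
from .spectra_io import SpectralDataset

__all__ = [
    "PcaModel",
    "LdaModel",
    "CvReport",
    "fit_pca",
    "fit_lda",
    "pca_lda_scores",
    "loocv_classify",
    "ld1_column",
]


def ld1_column(window: BandDefinition) -> str:
    """Feature-table column name for a band's LD1 score, e.g. ``ld1_1470_1700``."""
    return f"ld1_{window.lo:g}_{window.hi:g}".replace(".", "p")


@dataclass(frozen=True)
class PcaModel:
    """Principal components of mean-centered spectra.

    ``loadings`` has shape (n_components, n_wavenumbers), rows orthonormal,
    ordered by nonincreasing ``eigenvalues`` (sample variance along each
    component, ddof=1).
    """

    mean: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.mean) @ self.loadings.T


def fit_pca(matrix: np.ndarray, n_components: int) -> PcaModel:
    """Eigendecomposition of the sample covariance of mean-centered rows."""
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 subjects")
    limit = min(n - 1, p)
    if not 1 <= n_components <= limit:
        raise ValueError(
            f"n_components={n_components} out of range [1, {limit}] for a {n}x{p} matrix"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    model.fit(X)
    return PcaModel(
        mean=model.mean_,
        loadings=model.components_,
        eigenvalues=model.explained_variance_,
    )


@dataclass(frozen=True)
class LdaModel:
    """Two-class Fisher discriminant in PC-score space.

    ``direction`` is the unit vector maximizing the Fisher criterion
    J(w) = (wᵀ S_B w)/(wᵀ S_W w); for two classes this is the
    S_W⁻¹ (μ_case − μ_control) direction, oriented so the case-group mean
    LD1 exceeds the control mean.  ``threshold`` is the midpoint of the two
    class-mean scores (the equal-prior Gaussian boundary).
    """

    direction: np.ndarray
    mean_control: float
    mean_case: float
    ridge: float = 0.0

    @property
    def threshold(self) -> float:
        return 0.5 * (self.mean_control + self.mean_case)

    def project(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float) @ self.direction

    def predict(self, scores: np.ndarray) -> np.ndarray:
        """1 = case, 0 = control."""
        return (self.project(scores) > self.threshold).astype(int)


def fit_lda(scores: np.ndarray, labels: np.ndarray, ridge: str | float = "auto") -> LdaModel:
    """Fisher LDA for two classes: w ∝ S_W⁻¹ (μ₁ − μ₀), unit norm.

    ``ridge`` adds ε·I to the within-class scatter when it is near-singular
    (``"auto"``: ε = 1e-8·trace(S_W)/k only if needed).
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("scores must be (subjects x k) aligned with labels")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both classes must be present (labels 0 and 1)")
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    delta = mu1 - mu0
    if np.allclose(delta, 0.0):
        raise ValueError("no separation: identical class means, Fisher criterion is 0 everywhere")
    sw = np.zeros((X.shape[1], X.shape[1]))
    for cls, mu in ((0, mu0), (1, mu1)):
        d = X[y == cls] - mu
        sw += d.T @ d
    k = sw.shape[0]
    eps = 0.0
    if ridge == "auto":
        # regularize only when S_W is numerically rank-deficient
        if np.linalg.cond(sw) > 1e12 or not np.isfinite(np.linalg.cond(sw)):
            eps = 1e-8 * np.trace(sw) / k
    else:
        eps = float(ridge)
    try:
        w = np.linalg.solve(sw + eps * np.eye(k), delta)
    except np.linalg.LinAlgError:
        eps = max(eps, 1e-8 * np.trace(sw) / k) or 1e-12
        w = np.linalg.solve(sw + eps * np.eye(k), delta)
    w = w / np.linalg.norm(w)
    m0 = float((X[y == 0] @ w).mean())
    m1 = float((X[y == 1] @ w).mean())
    if m1 < m0:  # orient so cases score higher
        w, m0, m1 = -w, -m0, -m1
    return LdaModel(direction=w, mean_control=m0, mean_case=m1, ridge=eps)


def fisher_criterion(scores: np.ndarray, labels: np.ndarray, w: np.ndarray) -> float:
    """J(w) = (wᵀ S_B w) / (wᵀ S_W w) for two classes."""
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    mu0, mu1 = X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    d = mu1 - mu0
    sb = n0 * n1 / (n0 + n1) * np.outer(d, d)
    sw = np.zeros_like(sb)
    for cls, mu in ((0, mu0), (1, mu1)):
        dd = X[y == cls] - mu
        sw += dd.T @ dd
    w = np.asarray(w, dtype=float)
    return float(w @ sb @ w) / float(w @ sw @ w)


def _band_chain(matrix: np.ndarray, labels: np.ndarray, n_components: int):
    pca = fit_pca(matrix, n_components)
    pc = pca.transform(matrix)
    lda = fit_lda(pc, labels)
    return pca, lda


def pca_lda_scores(
    dataset: SpectralDataset,
    window: BandDefinition,
    n_components: int = 2,
    standardize: bool = True,
) -> np.ndarray:
    """Per-subject LD1 shape score for one diagnostic band.

    The band is baseline-corrected and area-normalized, reduced to
    ``n_components`` principal components, and projected onto the fitted
    Fisher direction.  With ``standardize=True`` scores are shifted/scaled
    to zero pooled mean and unit pooled variance (ddof=1).
    """
    labels = dataset.labels
    band = preprocess_band(dataset, window, normalize_after=True)
    matrix = band.to_matrix()
    pca, lda = _band_chain(matrix, labels, n_components)
    ld1 = lda.project(pca.transform(matrix))
    if standardize:
        sd = ld1.std(ddof=1)
        if sd > 0:
            ld1 = (ld1 - ld1.mean()) / sd
        else:
            ld1 = ld1 - ld1.mean()
    return ld1


@dataclass(frozen=True)
class CvReport:
    """Aggregate of held-out predictions from leave-one-out cross-validation."""

    tp: int
    fp: int
    tn: int
    fn: int
    predictions: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    @property
    def n_folds(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_folds

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n_folds": self.n_folds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def loocv_classify(
    dataset: SpectralDataset,
    window: BandDefinition,
    n_components: int = 2,
    refit_pca: bool = True,
) -> CvReport:
    """Leave-one-out cross-validation of the PCA-LDA band classifier.

    Each of the n subjects is held out once; the full chain is refit on the
    remaining n−1 and the held-out subject is classified by thresholding
    its LD1 score at the midpoint of the training class means.  With
    ``refit_pca=False`` the PCA (but never the LDA) is fit once on all
    subjects — a faster but leakage-prone variant kept only for comparison.
    """
    labels = dataset.labels
    n = len(dataset)
    if n < 4:
        raise ValueError(f"LOOCV needs n >= 4 subjects, got {n}")
    band = preprocess_band(dataset, window, normalize_after=True)
    matrix = band.to_matrix()
    shared_pca = None if refit_pca else fit_pca(matrix, n_components)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        y_tr = labels[train]
        if len(set(y_tr.tolist())) < 2:
            raise ValueError("a training fold lost one class entirely")
        X_tr = matrix[train]
        pca = shared_pca or fit_pca(X_tr, n_components)
        lda = fit_lda(pca.transform(X_tr), y_tr)
        preds[i] = lda.predict(pca.transform(matrix[i : i + 1]))[0]
    tp = int(((preds == 1) & (labels == 1)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    return CvReport(tp=tp, fp=fp, tn=tn, fn=fn, predictions=preds, labels=labels)
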