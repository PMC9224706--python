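"""Group tests, ROC/AUC evaluation, operating points, and logistic marker combination.

All ROC machinery follows the Mann–Whitney identity: the empirical AUC of
a score equals U/(n_case·n_control), the probability that a random case
outscores a random control (ties counted half).  Confidence intervals use
DeLong's asymptotic variance by default (deterministic) with a stratified
bootstrap as the alternative.  Markers for which controls score *higher*
can be negated up front so every reported AUC is ≥ 0.5 with the direction
recorded.

Marker combination is a maximum-likelihood logistic regression followed by
a deterministic bidirectional stepwise search minimizing AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "RocResult",
    "OperatingPoint",
    "LogisticModel",
    "wilcoxon_rank_sum",
    "roc_auc",
    "youden_threshold",
    "closest_topleft_threshold",
    "fit_logistic",
    "stepwise_select",
    "combined_marker_roc",
]


@dataclass(frozen=True)
class TestResult:
    """Two-sided test outcome with the method actually used."""

    statistic: float
    p_value: float
    method: Literal["exact", "normal-approximation"]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test, control vs case.

    Uses the exact null distribution when the pooled sample is small
    (n_x + n_y ≤ 20) and tie-free; otherwise the normal approximation with
    tie and continuity corrections.  The statistic reported is U for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size <= 20) and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="exact" if exact else "normal-approximation",
    )


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with AUC and a 95% confidence interval.

    ``thresholds`` are descending score cutoffs (predict case when
    score ≥ threshold); ``sensitivity``/``specificity`` are aligned with
    them, tracing the step curve from (0,0) to (1,1) in ROC space.
    """

    thresholds: np.ndarray = field(repr=False)
    sensitivity: np.ndarray = field(repr=False)
    specificity: np.ndarray = field(repr=False)
    auc: float
    ci_low: float
    ci_high: float
    n_case: int
    n_control: int
    ci_method: str = "delong"
    flipped: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC {self.auc} outside [0, 1]")


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank identity U/(n1·n0), ties counted half."""
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _delong_ci(scores: np.ndarray, labels: np.ndarray, level: float = 0.95):
    """DeLong variance of the empirical AUC via placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size

    def placements(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # fraction of b below each element of a, ties counted half
        order = np.sort(b)
        lo = np.searchsorted(order, a, side="left")
        hi = np.searchsorted(order, a, side="right")
        return (lo + hi) / (2.0 * b.size)

    v10 = placements(pos, neg)  # per-case placement
    v01 = 1.0 - placements(neg, pos)  # per-control placement
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), max(0.0, auc - half), min(1.0, auc + half)


def _bootstrap_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    level: float = 0.95,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
):
    rng = rng or np.random.default_rng(0)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(pos_idx, pos_idx.size), rng.choice(neg_idx, neg_idx.size)]
        )
        aucs[b] = _auc_mann_whitney(scores[take], labels[take])
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    ci_method: Literal["delong", "bootstrap"] = "delong",
    orient: bool = False,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> RocResult:
    """Empirical ROC curve and AUC with a 95% confidence interval.

    ``labels``: 1 = case, 0 = control.  With ``orient=True`` a marker whose
    raw AUC is below 0.5 is negated before analysis (``flipped`` records
    this), so the reported AUC is always ≥ 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    flipped = False
    if orient and _auc_mann_whitney(scores, labels) < 0.5:
        scores = -scores
        flipped = True
    # step curve over all unique thresholds, descending; predict case if score >= t
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate([[np.inf], uniq])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    for i, t in enumerate(thresholds):
        sens[i] = np.mean(pos >= t)
        spec[i] = np.mean(neg < t)
    auc = _auc_mann_whitney(scores, labels)
    if ci_method == "delong":
        _, lo, hi = _delong_ci(scores, labels)
    elif ci_method == "bootstrap":
        lo, hi = _bootstrap_ci(scores, labels, n_boot=n_boot, rng=rng)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        n_case=n1,
        n_control=n0,
        ci_method=ci_method,
        flipped=flipped,
    )


def _pick_operating_point(roc: RocResult, objective: np.ndarray, maximize: bool) -> OperatingPoint:
    obj = objective if maximize else -objective
    best = obj.max()
    # ties broken toward higher sensitivity
    candidates = np.flatnonzero(np.isclose(obj, best, rtol=0, atol=1e-12))
    idx = candidates[np.argmax(roc.sensitivity[candidates])]
    return OperatingPoint(
        threshold=float(roc.thresholds[idx]),
        sensitivity=float(roc.sensitivity[idx]),
        specificity=float(roc.specificity[idx]),
    )


def youden_threshold(roc: RocResult) -> OperatingPoint:
    """Operating point maximizing Youden's J = sensitivity + specificity − 1."""
    return _pick_operating_point(roc, roc.sensitivity + roc.specificity - 1.0, True)


def closest_topleft_threshold(roc: RocResult) -> OperatingPoint:
    """Operating point minimizing the squared distance to (FPR=0, TPR=1)."""
    dist2 = (1.0 - roc.sensitivity) ** 2 + (1.0 - roc.specificity) ** 2
    return _pick_operating_point(roc, dist2, False)


# ---------------------------------------------------------------------------
# logistic combination


@dataclass
class LogisticModel:
    """Maximum-likelihood logistic regression over named markers.

    ``coefficients`` maps marker name → log-odds per unit; ``separated``
    flags (quasi-)complete separation, detected as any standardized
    coefficient drifting beyond 15 in absolute value, in which case the
    usual MLE does not exist and the fit is flagged non-converged (a Firth
    penalized fit is available via ``fit_logistic(..., firth=True)``).
    """

    markers: list[str]
    intercept: float
    coefficients: dict[str, float]
    converged: bool
    separated: bool
    aic: float
    llf: float
    p_values: dict[str, float] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    trace: list[tuple[str, str, float]] = field(default_factory=list)
    firth: bool = False

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(features), self.intercept)
        for name, beta in self.coefficients.items():
            eta = eta + beta * features[name].to_numpy(dtype=float)
        return eta

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(features)))


def _drop_degenerate_columns(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove constant and exactly duplicated marker columns (design check)."""
    dropped: list[str] = []
    keep: list[str] = []
    seen: list[np.ndarray] = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if np.all(v == v[0]):
            dropped.append(col)
            continue
        if any(np.array_equal(v, u) for u in seen):
            dropped.append(col)
            continue
        seen.append(v)
        keep.append(col)
    return X[keep], dropped


def _firth_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth-penalized logistic MLE (Jeffreys prior), Newton iterations."""
    n, k = X.shape
    beta = np.zeros(k)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w  # leverages
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        ll += 0.5 * np.linalg.slogdet(info)[1]
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    eta = X @ beta
    llf = float(np.sum(y * eta - np.log1p(np.exp(eta))))  # unpenalized
    return beta, llf


def fit_logistic(
    features: pd.DataFrame,
    labels: Sequence[int],
    markers: Sequence[str] | None = None,
    firth: bool = False,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticModel:
    """Logistic regression of case/control labels on marker columns.

    Constant and exactly duplicated columns are dropped before fitting
    (recorded in ``dropped``).  Separation is flagged when any coefficient,
    on within-sample standardized scale, exceeds 15 in absolute value.
    """
    y = np.asarray(labels, dtype=float)
    if markers is None:
        markers = [c for c in features.columns if c not in ("subject_id", "group")]
    X = features[list(markers)].astype(float)
    X, dropped = _drop_degenerate_columns(X)
    kept = list(X.columns)
    if y.size <= len(kept) + 1:
        raise ValueError(
            f"n={y.size} too small for {len(kept)} coefficients plus intercept"
        )
    design = np.column_stack([np.ones(y.size), X.to_numpy()])
    if firth:
        beta, llf = _firth_fit(design, y, max_iter=max_iter, tol=tol)
        aic = 2 * (len(kept) + 1) - 2 * llf
        pvals: dict[str, float] = {}
        converged = True
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, design)
            try:
                res = model.fit(
                    disp=0, maxiter=max_iter, tol=tol, method="newton", warn_convergence=False
                )
            except np.linalg.LinAlgError:
                # singular Hessian, typically under complete separation
                res = model.fit(disp=0, maxiter=5 * max_iter, method="bfgs", warn_convergence=False)
            with np.errstate(all="ignore"):
                beta = res.params
                llf = float(res.llf)
                aic = float(res.aic)
                pvals = {name: float(p) for name, p in zip(kept, res.pvalues[1:])}
                converged = bool(res.mle_retvals.get("converged", True))
    scale = X.to_numpy().std(axis=0, ddof=1) if kept else np.array([])
    std_coef = beta[1:] * scale
    separated = bool(np.any(np.abs(std_coef) > 15.0)) and not firth
    return LogisticModel(
        markers=kept,
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(kept, beta[1:])},
        converged=converged and not separated,
        separated=separated,
        aic=float(aic),
        llf=llf,
        p_values=pvals,
        dropped=dropped,
        firth=firth,
    )


def stepwise_select(
    features: pd.DataFrame,
    labels: Sequence[int],
    markers: Sequence[str] | None = None,
    criterion: Literal["aic"] = "aic",
) -> LogisticModel:
    """Bidirectional stepwise logistic regression minimizing AIC.

    Starts from the full model; at each step evaluates every single-marker
    drop and re-add and takes the move with the lowest AIC, stopping when
    no move improves it.  Deterministic given marker order (ties resolved
    toward the smaller model, then first marker in column order).  The
    selection path is recorded in the returned model's ``trace`` as
    ``(action, marker, aic)`` tuples, AIC strictly decreasing.
    """
    if criterion != "aic":
        raise ValueError("only AIC selection is supported")
    y = np.asarray(labels, dtype=int)
    if markers is None:
        markers = [c for c in features.columns if c not in ("subject_id", "group")]
    markers = list(markers)
    if len(markers) < 2:
        raise ValueError("stepwise selection needs >= 2 candidate markers")

    cache: dict[frozenset, float] = {}

    def aic_of(subset: tuple[str, ...]) -> float:
        key = frozenset(subset)
        if key not in cache:
            if subset:
                cache[key] = fit_logistic(features, y, markers=subset).aic
            else:
                p = y.mean()
                ll = y.sum() * np.log(p) + (y.size - y.sum()) * np.log(1 - p) if 0 < p < 1 else 0.0
                cache[key] = float(2 - 2 * ll)
        return cache[key]

    current = tuple(markers)
    current_aic = aic_of(current)
    trace: list[tuple[str, str, float]] = [("start", "+".join(current) or "<null>", current_aic)]
    while True:
        moves: list[tuple[float, int, str, tuple[str, ...]]] = []
        for m in current:  # drops first => ties prefer the smaller model
            subset = tuple(v for v in current if v != m)
            moves.append((aic_of(subset), len(subset), f"drop {m}", subset))
        for m in markers:
            if m not in current:
                subset = tuple(v for v in markers if v in current or v == m)
                moves.append((aic_of(subset), len(subset), f"add {m}", subset))
        if not moves:
            break
        moves.sort(key=lambda t: (t[0], t[1]))
        best_aic, _, action, subset = moves[0]
        if best_aic < current_aic - 1e-10:
            current, current_aic = subset, best_aic
            trace.append((action.split()[0], action.split()[1], best_aic))
        else:
            break
    if current:
        model = fit_logistic(features, y, markers=current)
    else:
        p = float(y.mean())
        model = LogisticModel(
            markers=[], intercept=float(np.log(p / (1 - p))) if 0 < p < 1 else 0.0,
            coefficients={}, converged=True, separated=False,
            aic=aic_of(()), llf=-aic_of(()) / 2 + 1,
        )
    model.trace = trace
    return model


def combined_marker_roc(
    model: LogisticModel,
    features: pd.DataFrame,
    labels: Sequence[int],
    ci_method: Literal["delong", "bootstrap"] = "delong",
    rng: np.random.Generator | None = None,
) -> RocResult:
    """ROC of the fitted model's linear predictor (equivalently, its
    predicted probabilities — ROC is invariant to the logistic link)."""
    return roc_auc(model.linear_predictor(features), labels, ci_method=ci_method, rng=rng)
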