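"""Panel scoring and evaluation: logistic scores, ROC/AUC with bootstrap CIs,
Youden-optimal cutoffs, PCA projection, and the small-sample demographic tests
(Fisher exact, exact Mann-Whitney) used to compare the cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .containers import AbundanceMatrix
from .ranktests import exact_mann_whitney  # noqa: F401  (re-exported surface)

#: Cap on |coefficient| beyond which an ML logistic fit is treated as separated.
_COEF_CAP = 25.0


@dataclass
class LogisticPanelFit:
    """Per-sample fast-progressor probabilities from a logistic panel fit."""

    scores: np.ndarray
    coefficients: np.ndarray  # intercept first
    separated: bool


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    criterion: float
    sensitivity: float
    specificity: float


def fit_logistic_panel(marker_values: np.ndarray, labels: np.ndarray) -> LogisticPanelFit:
    """Maximum-likelihood logistic fit of class on marker values.

    ``marker_values`` is (n_samples, n_markers); ``labels`` is binary with 1 =
    fast progressor. Scores are fitted probabilities of the positive class.
    Under complete separation the ML estimate diverges; the fit falls back to
    a ridge-stabilised logistic model (capped coefficients) and is flagged.
    """
    X = np.atleast_2d(np.asarray(marker_values, dtype=float))
    if X.shape[0] != len(labels):
        X = X.T
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    if np.isnan(X).any():
        raise ValueError("marker submatrix contains missing values; impute or drop upstream")

    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = np.asarray(fit.params, dtype=float)
        if not np.all(np.isfinite(params)) or np.max(np.abs(params[1:])) > _COEF_CAP:
            raise np.linalg.LinAlgError("separation")
        scores = np.asarray(fit.predict(Xc), dtype=float)
    except Exception:
        separated = True
        clf = LogisticRegression(C=10.0, max_iter=5000)
        clf.fit(X, y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        scores = clf.predict_proba(X)[:, 1]
    return LogisticPanelFit(scores=scores, coefficients=params, separated=separated)


def roc_auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic, ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bootstrap_auc_ci(
    scores,
    labels,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling within each class."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
        )
        aucs[b] = roc_auc(s[idx], y[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def optimal_criterion(scores, labels) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    A sample is called positive when score >= criterion. Ties in J are broken
    toward the higher-specificity (larger) cutoff. Returns (criterion,
    sensitivity, specificity).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = (y == 1).sum()
    n0 = (y == 0).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    best = None
    for c in np.unique(s):
        sens = float((s[y == 1] >= c).mean())
        spec = float((s[y == 0] < c).mean())
        j = sens + spec - 1.0
        key = (j, spec, c)
        if best is None or key > best[0]:
            best = (key, (float(c), sens, spec))
    return best[1]


def evaluate_panel(
    marker_values: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> RocResult:
    """Logistic scores → AUC, bootstrap CI and Youden-optimal operating point."""
    fit = fit_logistic_panel(marker_values, labels)
    auc = roc_auc(fit.scores, labels)
    lo, hi = bootstrap_auc_ci(fit.scores, labels, n_boot=n_boot, level=level, seed=seed)
    crit, sens, spec = optimal_criterion(fit.scores, labels)
    return RocResult(auc=auc, ci_low=lo, ci_high=hi, criterion=crit,
                     sensitivity=sens, specificity=spec)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table: the total probability of all
    tables (with the observed margins) no more likely than the observed one."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be integers")
    return float(stats.fisher_exact(t.astype(int), alternative="two-sided")[1])


def pca_project(
    matrix: AbundanceMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the principal components of the panel matrix.

    Proteins are centered; samples are observations. Returns (scores indexed
    by sample with columns PC1..PCk, explained variance ratios). The matrix
    must be complete (impute upstream).
    """
    X = matrix.values.to_numpy().T  # samples × proteins
    if np.isnan(X).any():
        raise ValueError("matrix has missing values; impute before PCA")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples for PCA")
    k = min(n_components, min(X.shape))
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=matrix.sample_ids, columns=cols),
        pca.explained_variance_ratio_,
    )
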