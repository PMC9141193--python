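"""Elastic-net logistic marker panels evaluated by precision-recall AUC.

The classifier minimises the penalised logistic loss

    (1/n) sum_i log(1 + exp(-y_i x_i' b)) + lambda * (alpha*||b||_1
                                                      + (1-alpha)/2*||b||_2^2)

with the mixing parameter alpha interpolating between ridge (alpha=0) and
lasso (alpha=1).  lambda is chosen on a log-spaced grid descending from
lambda_max (the smallest penalty that zeroes every coefficient) by
stratified cross-validation maximising the average-precision estimate of
the precision-recall AUC.  Significance of a panel's PRAUC is assessed by
refitting under label permutation: p = (1 + #{perm >= observed}) / (1 + B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .genesets import bh_adjust

__all__ = [
    "ElasticNetModel",
    "ClassifierReport",
    "fit_elastic_net",
    "evaluate_prauc",
    "permutation_significance",
]


@dataclass
class ElasticNetModel:
    """A fitted elastic-net logistic panel, coefficients on the input scale."""

    predictors: list[str]
    alpha: float
    lam: float
    intercept: float
    coef: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    cv_folds: int
    seed: int
    lambda_grid: np.ndarray = field(repr=False, default=None)
    cv_prauc: np.ndarray = field(repr=False, default=None)

    @property
    def selected_predictors(self) -> list[str]:
        return [g for g, c in zip(self.predictors, self.coef) if c != 0]

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coef

    def predict_proba(self, X) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    def coefficients(self) -> pd.Series:
        return pd.Series(self.coef, index=self.predictors, name="coefficient")


@dataclass
class ClassifierReport:
    """PRAUC of a panel plus its label-permutation significance."""

    prauc: float
    selected_predictors: list[str]
    permutation_p: float
    n_permutations: int
    null_prauc: np.ndarray = field(repr=False, default=None)
    p_adj: float = np.nan


def evaluate_prauc(scores, y) -> float:
    """Average-precision estimate of the area under the PR curve.

    Positives are traversed in decreasing-score order and the precision
    at each positive's rank is averaged; tied scores are handled as
    blocks, every tie receiving the precision at the end of its block
    (so constant scores give the class prevalence).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    ap = 0.0
    tp = 0
    seen = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        block_pos = int(yy[i:j].sum())
        tp += block_pos
        seen = j
        if block_pos:
            ap += block_pos * (tp / seen)
        i = j
    return float(ap / n_pos)


def _lambda_grid(
    Xs: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int, min_ratio: float
) -> np.ndarray:
    n = len(y)
    ybar = y.mean()
    grad0 = np.abs(Xs.T @ (y - ybar)) / n
    lam_max = grad0.max() / max(alpha, 1e-3)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _sk_fit(Xs, y, alpha, lam, max_iter=5000, tol=1e-7):
    n = len(y)
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=float(alpha),
        C=1.0 / (n * lam),
        max_iter=max_iter,
        tol=tol,
    )
    clf.fit(Xs, y)
    return clf.coef_.ravel(), float(clf.intercept_[0])


def _path_fit(Xs, y, alpha, grid, max_iter=2000, tol=1e-5):
    """Warm-started coefficient path down a descending lambda grid."""
    n = len(y)
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=float(alpha),
        warm_start=True,
        max_iter=max_iter,
        tol=tol,
    )
    out = []
    for lam in grid:
        clf.C = 1.0 / (n * lam)
        clf.fit(Xs, y)
        out.append((clf.coef_.ravel().copy(), float(clf.intercept_[0])))
    return out


def fit_elastic_net(
    X,
    y,
    alpha: float = 0.35,
    cv_folds: int = 5,
    seed: int = 42,
    predictors: list[str] | None = None,
    n_lambda: int = 50,
    lambda_min_ratio: float = 1e-3,
    lam: float | None = None,
) -> ElasticNetModel:
    """Fit an elastic-net logistic panel with CV choice of lambda.

    ``X`` is samples x genes (DataFrame or array); predictors are
    standardized internally and coefficients reported on the original
    scale.  With ``lam`` given, the cross-validation is skipped and the
    model refit at that penalty (used for permutation nulls).
    """
    if isinstance(X, pd.DataFrame):
        predictors = predictors or [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        predictors = predictors or [f"g{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must lie in [0, 1]")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)
    Xs = (X - means) / sds

    grid = _lambda_grid(Xs, y, alpha, n_lambda, lambda_min_ratio)
    cv_scores = None
    if lam is None:
        folds = min(cv_folds, int(counts.min()))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        cv_scores = np.zeros((len(grid), folds))
        for f, (tr, va) in enumerate(skf.split(Xs, y)):
            for li, (coef, b0) in enumerate(_path_fit(Xs[tr], y[tr], alpha, grid)):
                s = b0 + Xs[va] @ coef
                cv_scores[li, f] = evaluate_prauc(s, y[va])
        mean_scores = cv_scores.mean(axis=1)
        # ties favour the larger (sparser) penalty: first index of the max
        lam = float(grid[int(np.argmax(mean_scores))])
    coef_s, b0 = _sk_fit(Xs, y, alpha, lam)
    coef = coef_s / sds
    intercept = b0 - float(np.sum(coef_s * means / sds))
    return ElasticNetModel(
        predictors=predictors,
        alpha=alpha,
        lam=float(lam),
        intercept=intercept,
        coef=coef,
        means=means,
        sds=sds,
        cv_folds=cv_folds,
        seed=seed,
        lambda_grid=grid,
        cv_prauc=cv_scores.mean(axis=1) if cv_scores is not None else None,
    )


def elastic_net_objective(model: ElasticNetModel, X, y) -> float:
    """Penalised logistic loss of a fitted model on its standardized scale."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Xs = (X - model.means) / model.sds
    beta = model.coef * model.sds
    b0 = model.intercept + float(np.sum(model.coef * model.means))
    eta = b0 + Xs @ beta
    yy = 2 * y - 1
    loss = np.mean(np.logaddexp(0.0, -yy * eta))
    pen = model.lam * (
        model.alpha * np.abs(beta).sum() + (1 - model.alpha) / 2 * np.sum(beta**2)
    )
    return float(loss + pen)


def permutation_significance(
    X,
    y,
    alpha: float = 0.35,
    cv_folds: int = 5,
    n_permutations: int = 100,
    seed: int = 42,
    X_eval=None,
    y_eval=None,
    n_lambda: int = 20,
) -> ClassifierReport:
    """Label-permutation significance of a panel's PRAUC.

    The panel is fit on (X, y) with CV choice of lambda and scored on the
    evaluation set (default: the training set).  Each permutation
    shuffles the training labels and reruns the identical procedure --
    including the cross-validated penalty choice, so the null preserves
    exchangeability -- scoring the permuted model on the same evaluation
    samples; p = (1 + #{perm PRAUC >= observed}) / (1 + B).
    """
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations")
    if isinstance(X, pd.DataFrame):
        X_arr = X.to_numpy(dtype=float)
        predictors = [str(c) for c in X.columns]
    else:
        X_arr = np.asarray(X, dtype=float)
        predictors = None
    y = np.asarray(y, dtype=float).ravel()
    if X_eval is None:
        X_eval_arr, y_eval_arr = X_arr, y
    else:
        X_eval_arr = (
            X_eval.to_numpy(dtype=float)
            if isinstance(X_eval, pd.DataFrame)
            else np.asarray(X_eval, dtype=float)
        )
        y_eval_arr = np.asarray(y_eval, dtype=float).ravel()
    model = fit_elastic_net(
        X_arr, y, alpha=alpha, cv_folds=cv_folds, seed=seed,
        predictors=predictors, n_lambda=n_lambda,
    )
    observed = evaluate_prauc(model.decision_function(X_eval_arr), y_eval_arr)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        yp = rng.permutation(y)
        m = fit_elastic_net(
            X_arr, yp, alpha=alpha, cv_folds=cv_folds, seed=seed, n_lambda=n_lambda
        )
        # against a held-out set the original evaluation labels stay put;
        # for training-set evaluation the permuted statistic mirrors the
        # observed one (each model scored on the labels it was fit to)
        y_null = y_eval_arr if X_eval is not None else yp
        null[b] = evaluate_prauc(m.decision_function(X_eval_arr), y_null)
    p = (1 + int((null >= observed).sum())) / (1 + n_permutations)
    return ClassifierReport(
        prauc=float(observed),
        selected_predictors=model.selected_predictors,
        permutation_p=float(p),
        n_permutations=n_permutations,
        null_prauc=null,
    )


def adjust_reports(reports: list[ClassifierReport]) -> list[ClassifierReport]:
    """BH-adjust permutation p-values across jointly evaluated panels."""
    adj = bh_adjust([r.permutation_p for r in reports])
    for r, a in zip(reports, adj):
        r.p_adj = float(a)
    return reports
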