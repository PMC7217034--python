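"""Logistic regression by IRLS, prediction, and Rubin's-rules pooling.

The analysis model throughout the package is a plain maximum-likelihood
logistic regression.  It is fitted by iteratively reweighted least squares
with a documented convergence contract (max |score| < 1e-8 or relative
deviance change < 1e-10, at most 100 iterations) and an automatic
ridge-penalized refit when the design is singular or the likelihood is
unbounded (separation).  Coefficient vectors from models fitted on multiple
imputations are combined by their arithmetic mean (Rubin's rules); the
within/between-imputation variance components are retained for reporting.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .cohort import CATEGORICAL, CompletedData, Cohort

__all__ = [
    "INTERCEPT",
    "PROB_EPS",
    "FitWarning",
    "design_matrix",
    "LogisticModel",
    "fit_logistic",
    "predict_design",
    "predict_logistic",
    "PooledModel",
    "pool_coefficients",
]

INTERCEPT = "(intercept)"
OUTCOME_DESIGN_NAME = "__outcome__"

#: predictions are clipped into the open unit interval by this margin
PROB_EPS = 1e-12


class FitWarning(UserWarning):
    """Raised-as-warning for degenerate fits resolved by a ridge refit."""


def design_matrix(X, specs, columns, exclude=(), outcome=None):
    """Build a design matrix with a leading intercept.

    Continuous and binary (0/1-coded) predictors enter as single columns;
    categorical predictors expand to reference-cell dummies on their fixed
    level order.  ``exclude`` lists predictor indices to drop (used when a
    column is itself the imputation target); ``outcome`` appends a trailing
    0/1 column so imputation models can condition on the outcome.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    cols = [np.ones(n)]
    names = [INTERCEPT]
    excl = set(int(e) for e in exclude)
    for j, (c, spec) in enumerate(zip(columns, specs)):
        if j in excl:
            continue
        if spec.kind == CATEGORICAL:
            for code in range(1, len(spec.levels)):
                cols.append((X[:, j] == code).astype(float))
                names.append(f"{c}[{spec.levels[code]}]")
        else:
            cols.append(X[:, j])
            names.append(c)
    if outcome is not None:
        cols.append(np.asarray(outcome, dtype=float))
        names.append(OUTCOME_DESIGN_NAME)
    return np.column_stack(cols), tuple(names)


@dataclass
class LogisticModel:
    """Coefficient vector on the logit scale (intercept first) with the
    design-column name list and, when available, the asymptotic covariance."""

    names: tuple
    coef: np.ndarray
    cov: np.ndarray | None = None
    converged: bool = True
    ridge: float = 0.0

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        if len(self.names) != self.coef.shape[0]:
            raise ValueError("coefficient/name length mismatch")
        if not np.all(np.isfinite(self.coef)):
            raise ValueError("non-finite coefficients")

    @property
    def se(self) -> np.ndarray:
        if self.cov is None:
            raise ValueError("no covariance available for this fit")
        return np.sqrt(np.diag(self.cov))


def _penalized_irls(D, y, lam, max_iter, score_tol, dev_tol):
    n, q = D.shape
    pen = np.full(q, float(lam))
    pen[0] = 0.0  # never penalize the intercept

    def objective(eta, beta):
        # -2 x (penalized log-likelihood)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return -2.0 * ll + float(pen @ beta**2)

    beta = np.zeros(q)
    eta = D @ beta
    dev = objective(eta, beta)
    converged = False
    for _ in range(max_iter):
        p = expit(eta)
        score = D.T @ (y - p) - pen * beta
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        W = p * (1.0 - p)
        H = D.T @ (D * W[:, None])
        H[np.diag_indices(q)] += pen
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            return beta, None, False, True
        new_beta = beta + step
        new_eta = D @ new_beta
        new_dev = objective(new_eta, new_beta)
        halvings = 0
        while (not np.isfinite(new_dev)) or new_dev > dev + 1e-10:
            halvings += 1
            if halvings > 20:
                break
            step = step * 0.5
            new_beta = beta + step
            new_eta = D @ new_beta
            new_dev = objective(new_eta, new_beta)
        if halvings > 20:
            break
        rel_change = abs(dev - new_dev) / (abs(dev) + 1.0)
        beta, eta, dev = new_beta, new_eta, new_dev
        if rel_change < dev_tol:
            converged = True
            break

    # fitted logits beyond +-20 (probabilities within 2e-9 of the boundary)
    # indicate an unbounded likelihood in practice
    separated = bool(lam == 0.0 and np.max(np.abs(eta)) > 20.0) if n else False
    p = expit(eta)
    W = np.clip(p * (1.0 - p), 1e-12, None)
    H = D.T @ (D * W[:, None])
    H[np.diag_indices(q)] += pen
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None
        separated = True
    return beta, cov, converged, separated


def fit_logistic(D, y, names=None, ridge=0.0, fallback_ridge=None,
                 max_iter=100, score_tol=1e-8, dev_tol=1e-10) -> LogisticModel:
    """Maximum-likelihood logistic regression of ``y`` on design ``D``.

    On separation, non-convergence or a singular design the fit is repeated
    with a small ridge penalty on the slopes (default ``1e-6 * n``) and a
    :class:`FitWarning` is issued.  ``y`` must contain both outcome levels.
    """
    D = np.atleast_2d(np.asarray(D, dtype=float))
    y = np.asarray(y, dtype=float)
    if D.shape[0] != y.shape[0]:
        raise ValueError("design/outcome length mismatch")
    if y.size == 0:
        raise ValueError("empty fitting data")
    present = set(np.unique(y))
    if not present <= {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    if len(present) < 2:
        raise ValueError("outcome has a single observed level; cannot fit")
    if D.shape[0] < D.shape[1] + 1:
        raise ValueError(
            f"too few rows ({D.shape[0]}) for {D.shape[1]} design columns"
        )
    if names is None:
        names = tuple(f"x{i}" for i in range(D.shape[1]))

    beta, cov, converged, separated = _penalized_irls(
        D, y, ridge, max_iter, score_tol, dev_tol
    )
    used = float(ridge)
    if ridge == 0.0 and (not converged or separated or cov is None):
        lam = float(fallback_ridge) if fallback_ridge is not None else 1e-6 * D.shape[0]
        warnings.warn(
            f"logistic fit degenerate (separation or singular design); "
            f"refitting with ridge {lam:.3g} on slopes",
            FitWarning,
            stacklevel=2,
        )
        beta, cov, converged, _ = _penalized_irls(
            D, y, lam, max_iter, score_tol, dev_tol
        )
        used = lam
        if not converged or cov is None:
            raise RuntimeError("penalized logistic fit failed to converge")
    return LogisticModel(tuple(names), beta, cov, converged, used)


def predict_design(model, D, names=None) -> np.ndarray:
    """Event probabilities ``expit(D @ coef)``, clipped into (0, 1)."""
    if names is not None and tuple(names) != tuple(model.names):
        missing = [c for c in model.names if c not in set(names)]
        raise ValueError(f"design columns do not match model; missing {missing!r}")
    eta = np.asarray(D, dtype=float) @ model.coef
    return np.clip(expit(eta), PROB_EPS, 1.0 - PROB_EPS)


def predict_logistic(model, data, rows=None) -> np.ndarray:
    """Predict from a :class:`CompletedData` (or a missing-free cohort)."""
    if isinstance(data, CompletedData):
        X, specs, columns = data.X, data.cohort.specs, data.cohort.columns
    elif isinstance(data, Cohort):
        if not data.observed.all():
            raise ValueError("cohort still has missing predictor cells; impute first")
        X, specs, columns = data.X, data.specs, data.columns
    else:
        raise TypeError("expected CompletedData or Cohort")
    D, names = design_matrix(X, specs, columns)
    if rows is not None:
        D = D[np.asarray(rows)]
    return predict_design(model, D, names)


@dataclass
class PooledModel:
    """Rubin's-rules consensus model: the element-wise mean of per-imputation
    coefficient vectors, plus within/between variance components (reporting
    only — inference on pooled performance is out of scope)."""

    names: tuple
    coef: np.ndarray
    models: list = field(repr=False, default_factory=list)
    within_variance: np.ndarray | None = None
    between_variance: np.ndarray | None = None
    total_variance: np.ndarray | None = None

    @property
    def n_imputations(self) -> int:
        return len(self.models)


def pool_coefficients(models) -> PooledModel:
    """Pool per-imputation coefficient vectors by their arithmetic mean."""
    models = list(models)
    if not models:
        raise ValueError("need at least one model to pool")
    names = tuple(models[0].names)
    for m in models[1:]:
        if tuple(m.names) != names:
            raise ValueError("misaligned design columns across imputations")
    B = np.stack([m.coef for m in models])
    coef = B.mean(axis=0)
    # the mean of identical entries is that entry, bit-exactly (floating
    # point K*a/K can drift one ulp)
    same = np.ptp(B, axis=0) == 0
    coef[same] = B[0, same]
    K = len(models)
    within = None
    if all(m.cov is not None for m in models):
        within = np.mean([np.diag(m.cov) for m in models], axis=0)
    between = B.var(axis=0, ddof=1) if K > 1 else np.zeros_like(coef)
    total = None
    if within is not None:
        total = within + (1.0 + 1.0 / K) * between
    return PooledModel(names, coef, models, within, between, total)
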