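"""Multiple imputation by chained equations (fully conditional specification).

One imputation draw starts from a random fill (each missing cell replaced by
a uniform draw from the column's observed values) and then cycles a fixed
number of times over the incomplete columns, in ascending order of missing
count.  Each column is regenerated from a Bayesian draw of its conditional
model given all other predictors and the outcome:

* continuous targets — normal linear regression with a scaled inverse-chi^2
  draw of the residual variance and a normal draw of the coefficients,
  followed by type-1 predictive mean matching (the imputed value is the
  observed value of one of the ``pmm_donors`` rows whose predicted mean is
  closest to the missing row's predicted mean);
* binary targets — a logistic fit, a normal draw of the coefficients around
  the MLE, then a Bernoulli draw of the missing cells;
* categorical targets — the multinomial analogue of the binary draw.

Outcome cells that were masked for cross-validation are treated as just
another incomplete (binary) column during cycling, so imputation models can
condition on the outcome without ever seeing validation outcomes; the imputed
outcome values are returned separately and flagged ephemeral.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import expit
from sklearn.base import BaseEstimator

from ._rng import generator, seed_sequence, substream
from .cohort import BINARY, CATEGORICAL, CONTINUOUS, Cohort, CompletedData
from .glm import design_matrix, fit_logistic

__all__ = [
    "ChainedEquationsImputer",
    "initialize_fill",
    "draw_continuous",
    "draw_binary",
    "draw_categorical",
    "impute_once",
    "impute_multiple",
]


def _initial_arrays(cohort: Cohort, rng: np.random.Generator):
    """Random starting fill: every missing cell gets a uniform draw from the
    column's observed values; observed cells are untouched."""
    X = cohort.X.copy()
    for j in range(cohort.n_predictors):
        obs = cohort.observed[:, j]
        miss = ~obs
        if miss.any():
            donors = X[obs, j]
            X[miss, j] = rng.choice(donors, size=int(miss.sum()), replace=True)
    y = cohort.y.copy()
    ymiss = np.isnan(y)
    if ymiss.any():
        donors = y[~ymiss]
        if donors.size == 0:
            raise ValueError("outcome column has no observed values")
        y[ymiss] = rng.choice(donors, size=int(ymiss.sum()), replace=True)
    return X, y


def initialize_fill(cohort: Cohort, rng=None) -> CompletedData:
    """Public wrapper around the starting fill, as a :class:`CompletedData`."""
    rng = generator(rng)
    X, y = _initial_arrays(cohort, rng)
    outcome = y if np.isnan(cohort.y).any() else None
    return CompletedData(cohort, X, 0, outcome)


def _draw_continuous(D, target, obs, pmm_donors, ridge, rng):
    """Bayesian-draw linear regression + type-1 predictive mean matching.

    Returns imputed values for the missing cells of ``target``; every value
    is a member of the column's observed value set (PMM closure).
    """
    Do = D[obs]
    to = target[obs]
    miss = ~obs
    m = int(miss.sum())
    n_obs, q = Do.shape
    if n_obs < pmm_donors:
        raise ValueError(
            f"{n_obs} observed rows but pmm_donors={pmm_donors}; not enough donors"
        )
    if n_obs < q + 2:
        raise ValueError(
            f"{n_obs} observed rows for {q} design columns; "
            "too few observations (consider increasing ridge)"
        )
    A = Do.T @ Do
    A[np.diag_indices(q)] += ridge
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular design after ridge augmentation"
        ) from err
    bhat = cho_solve((L, True), Do.T @ to)
    resid = to - Do @ bhat
    rss = float(resid @ resid)
    dfree = n_obs - q
    sigma2 = rss / rng.chisquare(dfree)
    z = rng.standard_normal(q)
    bstar = bhat + np.sqrt(sigma2) * solve_triangular(L.T, z, lower=False)

    eta_obs = Do @ bhat
    eta_mis = D[miss] @ bstar
    dist = np.abs(eta_mis[:, None] - eta_obs[None, :])
    # random permutation of donor order -> uniform tie-breaking at the
    # donor-pool boundary without an explicit tie scan
    perm = rng.permutation(n_obs)
    pool = np.argpartition(dist[:, perm], pmm_donors - 1, axis=1)[:, :pmm_donors]
    pick = pool[np.arange(m), rng.integers(0, pmm_donors, size=m)]
    return to[perm[pick]]


def _draw_beta_star(model, rng):
    cov = model.cov
    q = model.coef.shape[0]
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(cov + 1e-8 * np.eye(q))
    return model.coef + L @ rng.standard_normal(q)


def _draw_binary(D, target, obs, ridge, rng):
    """Bayesian logistic draw: MLE fit, normal coefficient draw around it,
    Bernoulli imputation of the missing cells."""
    to = target[obs]
    if len(set(np.unique(to))) < 2:
        raise ValueError("target column has a single observed level; cannot impute")
    # under complete separation the MLE fit falls back to a ridge penalty;
    # max(ridge, 0.1) keeps the coefficient draw concentrated enough that
    # imputations still track a perfectly predictive covariate
    model = fit_logistic(D[obs], to, fallback_ridge=max(ridge, 0.1))
    bstar = _draw_beta_star(model, rng)
    p = expit(D[~obs] @ bstar)
    m = p.shape[0]
    return (rng.random(m) < p).astype(float)


def _draw_categorical(D, target, obs, rng):
    """Bayesian multinomial-logistic draw (statsmodels MNLogit MLE with an
    asymptotic-normal parameter draw); falls back to observed-frequency
    draws, with a warning, when the multinomial fit fails."""
    import statsmodels.api as sm

    to = target[obs].astype(int)
    levels_obs = np.unique(to)
    m = int((~obs).sum())
    if levels_obs.size < 2:
        raise ValueError("target column has a single observed level; cannot impute")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # MNLogit wants contiguous 0..J-1 codes
            remap = {lev: i for i, lev in enumerate(levels_obs)}
            coded = np.vectorize(remap.get)(to)
            res = sm.MNLogit(coded, D[obs]).fit(disp=0, maxiter=200)
        params = np.asarray(res.params)          # q x (J-1)
        cov = np.asarray(res.cov_params())
        flat = params.ravel(order="F")
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(cov + 1e-8 * np.eye(cov.shape[0]))
        draw = flat + L @ rng.standard_normal(flat.shape[0])
        if not np.all(np.isfinite(draw)):
            raise np.linalg.LinAlgError("non-finite multinomial draw")
        Bs = draw.reshape(params.shape, order="F")
        eta = D[~obs] @ Bs
        logits = np.column_stack([np.zeros(m), eta])
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(m)
        idx = (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)
        return levels_obs[idx].astype(float)
    except (np.linalg.LinAlgError, ValueError, RuntimeError):
        warnings.warn(
            "multinomial imputation model failed; falling back to "
            "observed-frequency draws",
            UserWarning,
            stacklevel=2,
        )
        return rng.choice(target[obs], size=m, replace=True)


def _target_setup(target_col, completed: CompletedData):
    cohort = completed.cohort
    j = cohort.columns.index(target_col) if isinstance(target_col, str) else int(target_col)
    y = completed.outcome_imputed if completed.outcome_imputed is not None else cohort.y
    if np.isnan(y).any():
        raise ValueError("outcome must be complete (observed or imputed) "
                         "for conditional imputation models")
    D, _ = design_matrix(completed.X, cohort.specs, cohort.columns,
                         exclude=(j,), outcome=y)
    return j, D, cohort.observed[:, j]


def draw_continuous(target_col, completed: CompletedData, settings=None, rng=None):
    """One conditional draw for a continuous column: imputed values for its
    missing cells, via Bayesian linear regression + predictive mean matching
    against the current completed dataset."""
    settings = settings if settings is not None else ChainedEquationsImputer()
    settings._validate()
    j, D, obs = _target_setup(target_col, completed)
    if completed.cohort.specs[j].kind != CONTINUOUS:
        raise ValueError("target column is not continuous")
    return _draw_continuous(D, completed.X[:, j], obs,
                            int(settings.pmm_donors), float(settings.ridge),
                            generator(rng))


def draw_binary(target_col, completed: CompletedData, settings=None, rng=None):
    """One conditional draw for a binary column: Bernoulli imputations from
    a Bayesian logistic draw against the current completed dataset."""
    settings = settings if settings is not None else ChainedEquationsImputer()
    settings._validate()
    j, D, obs = _target_setup(target_col, completed)
    if completed.cohort.specs[j].kind != BINARY:
        raise ValueError("target column is not binary")
    return _draw_binary(D, completed.X[:, j], obs, float(settings.ridge),
                        generator(rng))


def draw_categorical(target_col, completed: CompletedData, settings=None, rng=None):
    """One conditional draw for a multi-level categorical column."""
    settings = settings if settings is not None else ChainedEquationsImputer()
    settings._validate()
    j, D, obs = _target_setup(target_col, completed)
    if completed.cohort.specs[j].kind != CATEGORICAL:
        raise ValueError("target column is not categorical")
    return _draw_categorical(D, completed.X[:, j], obs, generator(rng))


def _impute_once(cohort, n_cycles, pmm_donors, ridge, rng, k=0) -> CompletedData:
    X, y = _initial_arrays(cohort, rng)
    p = cohort.n_predictors

    targets = []
    for j in range(p):
        cnt = int((~cohort.observed[:, j]).sum())
        if cnt:
            targets.append((cnt, j))
    y_missing = int(np.isnan(cohort.y).sum())
    if y_missing:
        targets.append((y_missing, p))  # outcome visits last among ties
    targets.sort()

    if not targets:
        return CompletedData(cohort, X, k, None)

    for cycle in range(n_cycles):
        for _, j in targets:
            name = cohort.outcome_name if j == p else cohort.columns[j]
            try:
                if j == p:
                    D, _ = design_matrix(X, cohort.specs, cohort.columns)
                    obs = ~np.isnan(cohort.y)
                    y[~obs] = _draw_binary(D, y, obs, ridge, rng)
                else:
                    D, _ = design_matrix(
                        X, cohort.specs, cohort.columns, exclude=(j,), outcome=y
                    )
                    obs = cohort.observed[:, j]
                    kind = cohort.specs[j].kind
                    if kind == CONTINUOUS:
                        X[~obs, j] = _draw_continuous(
                            D, X[:, j], obs, pmm_donors, ridge, rng
                        )
                    elif kind == BINARY:
                        X[~obs, j] = _draw_binary(D, X[:, j], obs, ridge, rng)
                    else:
                        X[~obs, j] = _draw_categorical(D, X[:, j], obs, rng)
            except Exception as err:
                if hasattr(err, "add_note"):
                    err.add_note(
                        f"while imputing column {name!r} (cycle {cycle + 1})"
                    )
                raise
    outcome = y if y_missing else None
    return CompletedData(cohort, X, k, outcome)


class ChainedEquationsImputer(BaseEstimator):
    """Stochastic chained-equations imputer producing completed datasets.

    Parameters
    ----------
    n_cycles : int, default 5
        Fully-conditional-specification sweeps per draw.
    pmm_donors : int, default 5
        Donor-pool size for predictive mean matching of continuous targets.
    ridge : float, default 1e-5
        Non-negative regularization added to degenerate design cross-products
        (and, scaled up, to separated logistic fits).
    random_state : int, SeedSequence or Generator, optional
        Root seed; per-draw substreams are derived from it so draws are
        independent and order-stable.

    The defaults (five cycles, five donors) follow common chained-equations
    practice and are fully configurable.
    """

    def __init__(self, n_cycles=5, pmm_donors=5, ridge=1e-5, random_state=None):
        self.n_cycles = n_cycles
        self.pmm_donors = pmm_donors
        self.ridge = ridge
        self.random_state = random_state

    def _validate(self):
        if int(self.n_cycles) < 1:
            raise ValueError("n_cycles must be >= 1")
        if int(self.pmm_donors) < 1:
            raise ValueError("pmm_donors must be >= 1")
        if float(self.ridge) < 0:
            raise ValueError("ridge must be non-negative")

    def impute_once(self, cohort: Cohort, random_state=None, k=0) -> CompletedData:
        """One full chained-equations pass over ``cohort``."""
        self._validate()
        source = random_state if random_state is not None else self.random_state
        rng = generator(source)
        return _impute_once(
            cohort, int(self.n_cycles), int(self.pmm_donors), float(self.ridge),
            rng, k=k,
        )

    def impute_multiple(self, cohort: Cohort, n_imputations, random_state=None):
        """``n_imputations`` independent draws on order-stable substreams."""
        self._validate()
        if int(n_imputations) < 1:
            raise ValueError("n_imputations must be >= 1")
        source = random_state if random_state is not None else self.random_state
        ss = seed_sequence(source)
        return [
            self.impute_once(cohort, random_state=substream(ss, k), k=k)
            for k in range(int(n_imputations))
        ]


def impute_once(cohort, settings=None, random_state=None) -> CompletedData:
    """Functional wrapper over :meth:`ChainedEquationsImputer.impute_once`."""
    imputer = settings if settings is not None else ChainedEquationsImputer()
    return imputer.impute_once(cohort, random_state=random_state)


def impute_multiple(cohort, n_imputations, settings=None, random_state=None):
    """Functional wrapper over :meth:`ChainedEquationsImputer.impute_multiple`."""
    imputer = settings if settings is not None else ChainedEquationsImputer()
    return imputer.impute_multiple(cohort, n_imputations, random_state=random_state)
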