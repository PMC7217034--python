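"""Cross-validated calibration of logistic prediction rules under multiple
imputation, with outcome masking.

The driver implements three calibration strategies, all of which assess
predictions strictly out of sample: for every validation fold the complete
set of outcomes is removed *before* any imputation, the imputation model is
fitted jointly on calibration and (outcome-free) validation rows, the
prediction model is fitted on the imputed calibration rows with their true
outcomes, and the imputed outcome values for the fold are discarded.

* **Approach 1 (prediction averaging)** — K repetitions; each draws a fresh
  fold partition, generates a single imputation per fold, fits one model per
  fold, and predicts.  The K per-subject probabilities are pooled (mean by
  default).  This approximates the predictive density by averaging over both
  imputation and parameter draws.
* **Approach 2 (coefficient pooling)** — a single fixed fold partition; per
  fold, K imputations are generated, K models fitted, their coefficients
  pooled by Rubin's rules into one consensus model, and that single model is
  applied to each of the K imputed validation predictor sets.  The K
  predictions coincide for subjects with no missing predictors.
* **Approach 3** — as Approach 2, but the pooled model is applied once per
  subject to predictors whose missing cells are replaced by the per-cell
  mean (modal level for categoricals) over the K imputations.

All three coincide exactly at K = 1 under a shared seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._rng import PARTITION_KEY, generator, seed_sequence, substream
from .cohort import CATEGORICAL, Cohort, CompletedData
from .glm import design_matrix, fit_logistic, pool_coefficients, predict_design
from .impute import ChainedEquationsImputer

__all__ = [
    "FoldPartition",
    "make_folds",
    "mask_fold_outcomes",
    "PredictionMatrix",
    "MIPredictionCV",
    "cv_predict_one_pass",
    "approach1",
    "approach2",
    "approach3",
    "run_replicates",
    "average_completions",
]


@dataclass(frozen=True)
class FoldPartition:
    """Exhaustive, disjoint assignment of rows to folds ``1..L`` whose sizes
    differ by at most one."""

    assignment: np.ndarray
    L: int

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "assignment", a)
        if a.ndim != 1:
            raise ValueError("assignment must be a vector")
        labels, counts = np.unique(a, return_counts=True)
        if not np.array_equal(labels, np.arange(1, self.L + 1)):
            raise ValueError("every fold label 1..L must occur")
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes may differ by at most one")

    @property
    def n(self) -> int:
        return self.assignment.shape[0]

    def fold_rows(self, fold_id: int) -> np.ndarray:
        return self.assignment == int(fold_id)


def make_folds(n: int, L: int, rng=None) -> FoldPartition:
    """Uniformly random, unstratified partition of ``n`` rows into ``L``
    near-equal contiguous blocks of a random permutation."""
    n, L = int(n), int(L)
    if L < 2 or L > n:
        raise ValueError(f"need 2 <= L <= n, got L={L}, n={n}")
    rng = generator(rng)
    perm = rng.permutation(n)
    base, extra = divmod(n, L)
    assignment = np.empty(n, dtype=int)
    start = 0
    for fold in range(1, L + 1):
        size = base + (1 if fold <= extra else 0)
        assignment[perm[start:start + size]] = fold
        start += size
    return FoldPartition(assignment, L)


def mask_fold_outcomes(cohort: Cohort, partition: FoldPartition, fold_id: int) -> Cohort:
    """Remove (mask) the complete set of outcomes of one validation fold;
    predictor data are untouched."""
    if not 1 <= int(fold_id) <= partition.L:
        raise ValueError(f"fold_id must be in 1..{partition.L}")
    return cohort.mask_outcomes(partition.fold_rows(fold_id))


@dataclass
class PredictionMatrix:
    """n x K cross-validated event probabilities plus their pooled summary.

    ``pooled`` is exactly the stated row-wise summary (mean or median) of
    ``matrix``; ``fully_observed`` flags record status from the *original*
    cohort mask, for partitioned evaluation.
    """

    matrix: np.ndarray
    pooling: str
    fully_observed: np.ndarray
    row_id: object
    approach: int
    pooled: np.ndarray = None

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.pooling not in ("mean", "median"):
            raise ValueError("pooling must be 'mean' or 'median'")
        if np.any((self.matrix < 0) | (self.matrix > 1)):
            raise ValueError("probabilities outside [0, 1]")
        if self.pooled is None:
            if self.pooling == "mean":
                self.pooled = self.matrix.mean(axis=1)
            else:
                self.pooled = np.median(self.matrix, axis=1)
            # the summary of K identical values is that value, bit-exactly
            # (floating-point means of identical entries can drift one ulp)
            same = np.ptp(self.matrix, axis=1) == 0
            self.pooled[same] = self.matrix[same, 0]

    @property
    def n_imputations(self) -> int:
        return self.matrix.shape[1]


def _as_cohort(X, y) -> Cohort:
    if isinstance(X, Cohort):
        if y is not None:
            raise ValueError("pass either a Cohort or (X, y), not both")
        return X
    import pandas as pd

    return Cohort(pd.DataFrame(X), y)


def _fit_fold_model(completed_X, cohort, calib, fold_id):
    ycal = cohort.y[calib]
    if np.isnan(ycal).any():
        raise ValueError("calibration rows have masked outcomes")
    if len(set(np.unique(ycal))) < 2:
        raise ValueError(
            f"fold {fold_id}: calibration outcomes contain a single class"
        )
    D, names = design_matrix(completed_X, cohort.specs, cohort.columns)
    model = fit_logistic(D[calib], ycal, names=names)
    return model, D


def _check_fold_classes(cohort, fold, fold_id):
    if len(set(np.unique(cohort.y[~fold]))) < 2:
        raise ValueError(
            f"fold {fold_id}: calibration outcomes contain a single class"
        )


def _one_pass(cohort, partition, imputer, ss, pass_index):
    """One full cross-validatory sequence under single imputation."""
    n = cohort.n
    preds = np.empty(n)
    for j in range(1, partition.L + 1):
        fold = partition.fold_rows(j)
        _check_fold_classes(cohort, fold, j)
        masked = mask_fold_outcomes(cohort, partition, j)
        comp = imputer.impute_once(masked, random_state=substream(ss, pass_index, j))
        calib = ~fold
        model, D = _fit_fold_model(comp.X, cohort, calib, j)
        preds[fold] = predict_design(model, D[fold])
        # comp.outcome_imputed (the fold's imputed outcomes) is discarded here
    return preds


def _approach1(cohort, K, L, imputer, ss, partition):
    n = cohort.n
    matrix = np.empty((n, K))
    partitions = []
    for k in range(K):
        part = partition if partition is not None else make_folds(
            n, L, generator(substream(ss, k, PARTITION_KEY))
        )
        partitions.append(part)
        matrix[:, k] = _one_pass(cohort, part, imputer, ss, k)
    return matrix, partitions


def average_completions(completions) -> np.ndarray:
    """Per-cell average of K completed matrices: arithmetic mean for
    continuous and 0/1 binary columns, modal level (ties broken toward the
    first level in spec order) for categoricals."""
    completions = list(completions)
    if not completions:
        raise ValueError("need at least one completed dataset")
    cohort = completions[0].cohort
    stack = np.stack([c.X for c in completions])
    avg = stack.mean(axis=0)
    # cells identical across draws (every observed cell) stay bit-exact
    same = np.ptp(stack, axis=0) == 0
    avg[same] = stack[0][same]
    for j, spec in enumerate(cohort.specs):
        if spec.kind == CATEGORICAL:
            codes = stack[:, :, j]
            counts = np.stack(
                [(codes == lev).sum(axis=0) for lev in range(len(spec.levels))]
            )
            avg[:, j] = counts.argmax(axis=0)  # argmax takes the first max
    return avg


def _approach23(cohort, K, L, imputer, ss, partition, mean_impute):
    n = cohort.n
    part = partition if partition is not None else make_folds(
        n, L, generator(substream(ss, 0, PARTITION_KEY))
    )
    matrix = np.empty((n, K))
    averaged = np.empty(n) if mean_impute else None
    pooled_models = []
    for j in range(1, part.L + 1):
        fold = part.fold_rows(j)
        calib = ~fold
        _check_fold_classes(cohort, fold, j)
        masked = mask_fold_outcomes(cohort, part, j)
        comps = [
            imputer.impute_once(masked, random_state=substream(ss, k, j), k=k)
            for k in range(K)
        ]
        models = []
        designs = []
        for comp in comps:
            model, D = _fit_fold_model(comp.X, cohort, calib, j)
            models.append(model)
            designs.append(D)
        pooled = pool_coefficients(models)
        pooled_models.append(pooled)
        for k in range(K):
            matrix[fold, k] = predict_design(pooled, designs[k][fold])
        if mean_impute:
            Xavg = average_completions(comps)
            D, names = design_matrix(Xavg, cohort.specs, cohort.columns)
            averaged[fold] = predict_design(pooled, D[fold], names)
    return matrix, averaged, part, pooled_models


class MIPredictionCV(BaseEstimator):
    """Cross-validated calibration of a logistic prediction rule on a cohort
    with missing predictor values, by one of three multiple-imputation
    strategies.

    This estimator is transductive: :meth:`fit` runs the full
    outcome-masked cross-validation on the supplied cohort and stores the
    out-of-sample probabilities; :meth:`fit_predict` returns them.

    Parameters
    ----------
    approach : {1, 2, 3}
        1 — prediction averaging over K singly imputed cross-validations;
        2 — Rubin's-rules coefficient pooling over K imputations per fold;
        3 — approach 2's pooled model applied to mean-imputed predictors.
    n_imputations : int
        Number of imputations (approach 1: repetitions) K.
    n_folds : int
        Cross-validation fold count L.
    pooling : {"mean", "median"}
        Row-wise summary of the K probabilities.
    n_cycles, pmm_donors, ridge
        Chained-equations imputer settings (see
        :class:`~cvmipred.impute.ChainedEquationsImputer`).
    random_state : int, SeedSequence or Generator
        Root seed; substreams are keyed by (repetition, fold) so results do
        not depend on execution order.

    Attributes
    ----------
    prediction_matrix_ : PredictionMatrix
    predictions_ : ndarray of shape (n,)
        Pooled cross-validated event probabilities.
    record_status_ : ndarray of bool
        True where the subject's predictors are fully observed.
    partition_ / partitions_
        The fold partition(s) actually used.
    """

    def __init__(self, approach=1, n_imputations=10, n_folds=10, pooling="mean",
                 n_cycles=5, pmm_donors=5, ridge=1e-5, random_state=None):
        self.approach = approach
        self.n_imputations = n_imputations
        self.n_folds = n_folds
        self.pooling = pooling
        self.n_cycles = n_cycles
        self.pmm_donors = pmm_donors
        self.ridge = ridge
        self.random_state = random_state

    def _imputer(self) -> ChainedEquationsImputer:
        return ChainedEquationsImputer(
            n_cycles=self.n_cycles, pmm_donors=self.pmm_donors, ridge=self.ridge
        )

    def fit(self, X, y=None, partition=None):
        cohort = _as_cohort(X, y)
        ss = seed_sequence(self.random_state)
        self._fit_cohort(cohort, partition, ss)
        return self

    def _fit_cohort(self, cohort, partition, ss):
        if int(self.approach) not in (1, 2, 3):
            raise ValueError("approach must be 1, 2 or 3")
        if int(self.n_imputations) < 1:
            raise ValueError("n_imputations must be >= 1")
        if self.pooling not in ("mean", "median"):
            raise ValueError("pooling must be 'mean' or 'median'")
        if np.isnan(cohort.y).any():
            raise ValueError(
                "outcome must be fully observed for cross-validated calibration"
            )
        imputer = self._imputer()
        K = int(self.n_imputations)
        L = int(self.n_folds)
        approach = int(self.approach)
        if approach == 1:
            matrix, parts = _approach1(cohort, K, L, imputer, ss, partition)
            self.partitions_ = parts
            self.partition_ = parts[0] if partition is not None else None
        else:
            matrix, averaged, part, pooled = _approach23(
                cohort, K, L, imputer, ss, partition, mean_impute=(approach == 3)
            )
            if approach == 3:
                matrix = np.tile(averaged[:, None], (1, K))
            self.partition_ = part
            self.partitions_ = [part]
            self.pooled_models_ = pooled
        self.prediction_matrix_ = PredictionMatrix(
            matrix, self.pooling, cohort.fully_observed, cohort.row_id,
            int(self.approach),
        )
        self.predictions_ = self.prediction_matrix_.pooled
        self.record_status_ = cohort.fully_observed
        self.n_features_in_ = cohort.n_predictors
        return self

    def fit_predict(self, X, y=None, partition=None) -> np.ndarray:
        self.fit(X, y, partition=partition)
        return self.predictions_


# ---------------------------------------------------------------------------
# functional wrappers (operate directly on a Cohort)
# ---------------------------------------------------------------------------

def cv_predict_one_pass(cohort, partition, imputer=None, random_state=None):
    """Single-imputation cross-validated predictions for a fixed partition."""
    imputer = imputer if imputer is not None else ChainedEquationsImputer()
    ss = seed_sequence(random_state)
    if np.isnan(cohort.y).any():
        raise ValueError("outcome must be fully observed")
    return _one_pass(cohort, partition, imputer, ss, 0)


def _run_approach(cohort, approach, n_imputations, n_folds, pooling, imputer,
                  random_state, partition):
    params = imputer.get_params() if imputer is not None else {}
    params.pop("random_state", None)
    est = MIPredictionCV(
        approach=approach, n_imputations=n_imputations, n_folds=n_folds,
        pooling=pooling, random_state=random_state, **params,
    )
    est.fit(cohort, partition=partition)
    return est.prediction_matrix_


def approach1(cohort, n_imputations, n_folds=10, pooling="mean", imputer=None,
              random_state=None, partition=None) -> PredictionMatrix:
    """Prediction averaging over K singly imputed cross-validations."""
    return _run_approach(cohort, 1, n_imputations, n_folds, pooling, imputer,
                         random_state, partition)


def approach2(cohort, n_imputations, n_folds=10, pooling="mean", imputer=None,
              random_state=None, partition=None) -> PredictionMatrix:
    """Rubin's-rules coefficient pooling with a fixed fold partition."""
    return _run_approach(cohort, 2, n_imputations, n_folds, pooling, imputer,
                         random_state, partition)


def approach3(cohort, n_imputations, n_folds=10, pooling="mean", imputer=None,
              random_state=None, partition=None) -> PredictionMatrix:
    """Pooled coefficients applied to mean-imputed predictors."""
    return _run_approach(cohort, 3, n_imputations, n_folds, pooling, imputer,
                         random_state, partition)


def run_replicates(cohort, approach, n_imputations, n_folds=10, n_replicates=10,
                   pooling="mean", imputer=None, random_state=None,
                   partition=None):
    """Independent full repetitions of an approach (fresh folds and
    imputations per replicate, on keyed substreams); returns one
    :class:`PredictionMatrix` per replicate, rows aligned by row id."""
    if int(n_replicates) < 1:
        raise ValueError("n_replicates must be >= 1")
    ss = seed_sequence(random_state)
    params = imputer.get_params() if imputer is not None else {}
    params.pop("random_state", None)
    cohort = _as_cohort(cohort, None)
    out = []
    for r in range(int(n_replicates)):
        est = MIPredictionCV(
            approach=approach, n_imputations=n_imputations, n_folds=n_folds,
            pooling=pooling, **params,
        )
        est._fit_cohort(cohort, partition, substream(ss, r))
        out.append(est.prediction_matrix_)
    return out
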