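"""Summary measures for replicated cross-validated predictions.

Three measures, each reported on three partitions of the subjects — all
rows, fully observed records, and partially observed records (record status
comes from the original missingness mask; models are always calibrated on
the full data, so this is *not* complete-case analysis):

* the per-replicate Brier score ``B_r = mean((P_ir - Y_i)^2)`` and its mean
  over replicates;
* the imputation-variation measure ``R``: per subject, deviations of the
  replicate predictions from the subject's replicate mean; deviations of
  subjects whose mean prediction lies outside [0.2, 0.8] are discarded
  (between-replicate spread of a probability is approximately homoscedastic
  inside that band); R = (90th - 10th percentile of the surviving pooled
  deviations) x 100;
* the signed bias ``mean(P_ir - P_i)`` against known true probabilities
  (simulation only).

A partition with no rows (or fully filtered out) yields an explicit ``None``,
never a silent zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort

__all__ = [
    "PARTITIONS",
    "ReplicateSet",
    "EvaluationSummary",
    "brier_score",
    "mean_brier",
    "variation_measure",
    "bias_measure",
    "evaluate_replicates",
]

PARTITIONS = ("all", "fully_observed", "partially_observed")


@dataclass
class ReplicateSet:
    """n x R matrix of pooled predictions from R replicate analyses, with
    the outcome vector, record-status flags and (optionally) the simulated
    true event probabilities."""

    predictions: np.ndarray
    outcomes: np.ndarray
    fully_observed: np.ndarray
    true_probabilities: np.ndarray | None = None

    def __post_init__(self):
        self.predictions = np.atleast_2d(np.asarray(self.predictions, dtype=float))
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        self.fully_observed = np.asarray(self.fully_observed, dtype=bool)
        n = self.predictions.shape[0]
        if self.outcomes.shape != (n,) or self.fully_observed.shape != (n,):
            raise ValueError("replicate-set component lengths disagree")
        if np.any((self.predictions < 0) | (self.predictions > 1)):
            raise ValueError("predictions outside [0, 1]")
        if not set(np.unique(self.outcomes)) <= {0.0, 1.0}:
            raise ValueError("outcomes must be 0/1")
        if self.true_probabilities is not None:
            self.true_probabilities = np.asarray(self.true_probabilities, dtype=float)
            if self.true_probabilities.shape != (n,):
                raise ValueError("true-probability vector has wrong length")

    @classmethod
    def from_prediction_matrices(cls, prediction_matrices, cohort: Cohort,
                                 true_probabilities=None) -> "ReplicateSet":
        pms = list(prediction_matrices)
        preds = np.column_stack([pm.pooled for pm in pms])
        return cls(preds, cohort.y, cohort.fully_observed, true_probabilities)

    @property
    def n_replicates(self) -> int:
        return self.predictions.shape[1]

    def partition_mask(self, partition: str) -> np.ndarray:
        if partition == "all":
            return np.ones(self.predictions.shape[0], dtype=bool)
        if partition == "fully_observed":
            return self.fully_observed
        if partition == "partially_observed":
            return ~self.fully_observed
        raise ValueError(f"unknown partition {partition!r}")


def brier_score(predictions, outcomes) -> float:
    """Mean squared difference between predicted probability and outcome."""
    predictions = np.asarray(predictions, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if predictions.size == 0:
        raise ValueError("empty input to brier_score")
    if predictions.shape != outcomes.shape:
        raise ValueError("length mismatch")
    return float(np.mean((predictions - outcomes) ** 2))


def mean_brier(replicate_set: ReplicateSet) -> dict:
    """Per-replicate Brier scores and their mean, per partition.  Empty
    partitions are flagged unavailable (``mean`` is ``None``)."""
    out = {}
    for part in PARTITIONS:
        mask = replicate_set.partition_mask(part)
        if not mask.any():
            out[part] = {"per_replicate": None, "mean": None, "n_rows": 0}
            continue
        scores = [
            brier_score(replicate_set.predictions[mask, r],
                        replicate_set.outcomes[mask])
            for r in range(replicate_set.n_replicates)
        ]
        out[part] = {
            "per_replicate": scores,
            "mean": float(np.mean(scores)),
            "n_rows": int(mask.sum()),
        }
    return out


def variation_measure(replicate_set: ReplicateSet) -> dict:
    """Percentile-spread measure R per partition.

    Per subject, deviations ``D_ir = P_ir - mean_r(P_ir)``; subjects with a
    replicate-mean prediction strictly below 0.2 or strictly above 0.8
    contribute no deviations (the bounds themselves are retained).  R is the
    (90th - 10th) percentile span of the surviving pooled deviations, as a
    percentage, using linear-interpolation (type 7) quantiles.
    """
    if replicate_set.n_replicates < 2:
        raise ValueError("variation measure needs at least two replicates")
    P = replicate_set.predictions
    row_mean = P.mean(axis=1)
    keep = (row_mean >= 0.2) & (row_mean <= 0.8)
    deviations = P - row_mean[:, None]
    out = {}
    for part in PARTITIONS:
        mask = replicate_set.partition_mask(part) & keep
        if not mask.any():
            out[part] = None
            continue
        d = deviations[mask].ravel()
        q10, q90 = np.quantile(d, [0.10, 0.90], method="linear")
        out[part] = float((q90 - q10) * 100.0)
    return out


def bias_measure(replicate_set: ReplicateSet) -> dict:
    """Mean signed deviation from the true probabilities, per replicate and
    averaged over replicates, per partition."""
    if replicate_set.true_probabilities is None:
        raise ValueError("bias measure needs true probabilities")
    out = {}
    for part in PARTITIONS:
        mask = replicate_set.partition_mask(part)
        if not mask.any():
            out[part] = {"per_replicate": None, "mean": None, "n_rows": 0}
            continue
        per = [
            float(np.mean(replicate_set.predictions[mask, r]
                          - replicate_set.true_probabilities[mask]))
            for r in range(replicate_set.n_replicates)
        ]
        out[part] = {
            "per_replicate": per,
            "mean": float(np.mean(per)),
            "n_rows": int(mask.sum()),
        }
    return out


@dataclass
class EvaluationSummary:
    brier: dict
    variation: dict | None
    bias: dict | None
    n_replicates: int

    def record(self, partition: str) -> dict:
        """Flat per-partition record (None for unavailable summaries)."""
        rec = {
            "partition": partition,
            "n_rows": self.brier[partition]["n_rows"],
            "brier": self.brier[partition]["mean"],
            "R": self.variation[partition] if self.variation is not None else None,
            "bias": self.bias[partition]["mean"] if self.bias is not None else None,
            "n_replicates": self.n_replicates,
        }
        return rec


def evaluate_replicates(replicate_set: ReplicateSet) -> EvaluationSummary:
    """All summary measures for one replicated analysis."""
    variation = (
        variation_measure(replicate_set)
        if replicate_set.n_replicates >= 2 else None
    )
    bias = (
        bias_measure(replicate_set)
        if replicate_set.true_probabilities is not None else None
    )
    return EvaluationSummary(
        brier=mean_brier(replicate_set),
        variation=variation,
        bias=bias,
        n_replicates=replicate_set.n_replicates,
    )
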