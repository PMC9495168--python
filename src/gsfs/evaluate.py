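"""Reference/validation partitioning and prediction metrics.

Accuracy is the Pearson correlation between DRP and GEBV on the
validation set, divided by the square root of the mean DRP reliability
(the correction for the DRP itself being a noisy proxy of the true
breeding value).  Bias is the ordinary least-squares slope of DRP on
GEBV; 1 indicates no over/under-dispersion of the predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import PhenotypeTable

__all__ = [
    "EvaluationReport",
    "partition_population",
    "prediction_accuracy",
    "prediction_bias",
    "evaluate_predictions",
]


@dataclass
class EvaluationReport:
    accuracy: float
    bias: float
    n_validation: int
    mean_reliability: float
    raw_correlation: float

    def __post_init__(self) -> None:
        if self.n_validation < 2:
            raise ValueError("validation set must have at least 2 records")
        if not np.isfinite(self.accuracy):
            raise ValueError("non-finite accuracy")


def partition_population(
    table: PhenotypeTable,
    cutoff_year: int = 2013,
    min_reliability: float = 0.40,
) -> tuple[np.ndarray, np.ndarray]:
    """Split by birth year; filter low-reliability validation records.

    Reference: born strictly before ``cutoff_year``.  Validation: born
    in or after the cutoff *and* DRP reliability >= ``min_reliability``
    (the reliability filter applies to the validation set only).
    Returns (reference ids, validation ids).
    """
    years = table.birth_year
    r2 = table.reliability
    ids = table.ids
    ref = ids[years < cutoff_year]
    val = ids[(years >= cutoff_year) & (r2 >= min_reliability)]
    if ref.size == 0:
        raise ValueError("empty reference population")
    if val.size == 0:
        raise ValueError("empty validation population")
    return ref, val


def prediction_accuracy(
    drp_val: np.ndarray,
    gebv_val: np.ndarray,
    reliabilities_val: np.ndarray,
) -> float:
    """corr(DRP, GEBV) / sqrt(mean reliability) over the validation set."""
    drp = np.asarray(drp_val, dtype=float)
    gebv = np.asarray(gebv_val, dtype=float)
    r2 = np.asarray(reliabilities_val, dtype=float)
    if drp.shape[0] < 2:
        raise ValueError("need at least 2 validation records")
    if np.std(drp) == 0 or np.std(gebv) == 0:
        raise ValueError("constant DRP or GEBV; correlation undefined")
    corr = float(stats.pearsonr(drp, gebv).statistic)
    return corr / float(np.sqrt(np.mean(r2)))


def prediction_bias(drp_val: np.ndarray, gebv_val: np.ndarray) -> float:
    """OLS slope of DRP regressed on GEBV (1 = unbiased dispersion)."""
    drp = np.asarray(drp_val, dtype=float)
    gebv = np.asarray(gebv_val, dtype=float)
    if np.var(gebv) == 0:
        raise ValueError("constant GEBV; regression slope undefined")
    cov = float(np.cov(drp, gebv, ddof=1)[0, 1])
    return cov / float(np.var(gebv, ddof=1))


def evaluate_predictions(
    drp_val: np.ndarray,
    gebv_val: np.ndarray,
    reliabilities_val: np.ndarray,
) -> EvaluationReport:
    corr = float(stats.pearsonr(
        np.asarray(drp_val, float), np.asarray(gebv_val, float)
    ).statistic)
    return EvaluationReport(
        accuracy=prediction_accuracy(drp_val, gebv_val, reliabilities_val),
        bias=prediction_bias(drp_val, gebv_val),
        n_validation=len(np.asarray(drp_val)),
        mean_reliability=float(np.mean(reliabilities_val)),
        raw_correlation=corr,
    )
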