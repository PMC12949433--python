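"""Model-performance measures for the variable-selection benchmark.

Predictive accuracy is summarised by test-set RMSE and the calibration slope
(CSL: the OLS slope of observed outcomes on predictions; ideal value 1).
Selection quality uses the confusion counts over all p + c candidate
variables — every protein plus every confounder, intercept excluded — where
"selected" means a stored coefficient that is exactly nonzero (hub proteins,
being unpenalised, always count as selected) and "true" means a nonzero
generating coefficient (all confounders are true since ζ is nonzero).  The
counts feed

    F1  = 2·TP / (2·TP + FP + FN),
    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with MCC undefined (NaN) whenever a marginal factor of the denominator is
zero — as happens for ridge regression, which selects everything.  Replicate
means of MCC are taken over defined values only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class EvalReport:
    rmse: float
    csl: float
    f1: float
    mcc: float  # NaN when undefined
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse, "csl": self.csl, "f1": self.f1, "mcc": self.mcc,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        }


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def calibration_slope(y_true, y_pred) -> float:
    """OLS slope of y_true on y_pred (with intercept); NaN if predictions
    are constant."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    xc = y_pred - y_pred.mean()
    denom = float(xc @ xc)
    if denom <= 1e-30:
        warnings.warn(
            "constant predictions: calibration slope undefined",
            RuntimeWarning, stacklevel=2,
        )
        return float("nan")
    return float(xc @ (y_true - y_true.mean()) / denom)


def selection_counts(
    selected: np.ndarray, truth: np.ndarray
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) over the candidate set.

    ``selected`` and ``truth`` are boolean masks over the same ordered
    candidate list (confounders plus proteins, intercept excluded).
    """
    selected = np.asarray(selected, dtype=bool).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if selected.size != truth.size:
        raise ValueError("selected and truth masks differ in length")
    tp = int(np.sum(selected & truth))
    fp = int(np.sum(selected & ~truth))
    tn = int(np.sum(~selected & ~truth))
    fn = int(np.sum(~selected & truth))
    return tp, fp, tn, fn


def counts_from_coefficients(
    coef: np.ndarray, true_support_mask: np.ndarray
) -> tuple[int, int, int, int]:
    """Selection counts from a candidate-aligned coefficient vector.

    A coefficient counts as selected iff it is exactly nonzero as stored
    (the coordinate solver produces exact zeros; no epsilon thresholding).
    """
    coef = np.asarray(coef, dtype=float).ravel()
    return selection_counts(coef != 0, true_support_mask)


def f1_and_mcc(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float]:
    """F1 and MCC from confusion counts; MCC is NaN when its denominator is 0."""
    for v in (tp, fp, tn, fn):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    denom_f1 = 2 * tp + fp + fn
    f1 = 2.0 * tp / denom_f1 if denom_f1 > 0 else float("nan")
    marginals = [tp + fp, tp + fn, tn + fp, tn + fn]
    if any(m == 0 for m in marginals):
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(math.prod(marginals))
    return float(f1), float(mcc)


def evaluate(
    y_true,
    y_pred,
    coef: np.ndarray,
    true_support_mask: np.ndarray,
    target_mean=None,
) -> EvalReport:
    """One fitted model on one test set: RMSE, CSL, F1, MCC and counts.

    When the noiseless regression surface of a simulated test set is known,
    pass it as ``target_mean``: RMSE is then measured against it (pure
    estimation error, excluding the irreducible noise), while the calibration
    slope always uses the observed outcomes.
    """
    rmse_target = y_true if target_mean is None else target_mean
    tp, fp, tn, fn = counts_from_coefficients(coef, true_support_mask)
    f1, mcc = f1_and_mcc(tp, fp, tn, fn)
    return EvalReport(
        rmse=rmse(rmse_target, y_pred),
        csl=calibration_slope(y_true, y_pred),
        f1=f1,
        mcc=mcc,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def nanmean_sd(values) -> tuple[float, float]:
    """Mean and SD over defined (non-NaN) entries; (nan, nan) if none."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return float("nan"), float("nan")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
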