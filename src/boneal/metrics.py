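"""Segmentation and regression evaluation statistics.

Mask agreement is summarized by Dice, sensitivity and specificity computed
from per-pixel confusion counts (foreground = positive). Age agreement is
summarized by MAE and RMSE in months and by Lin's concordance correlation
coefficient (CCC), which penalizes both imprecision and location/scale bias
— it equals 1 only when predictions match observations exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np


class DegenerateInputError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass(frozen=True)
class RegressionEvalReport:
    """MAE/RMSE in months plus CCC for one cohort."""

    cohort: str  # "all" | "male" | "female"
    mae: float
    rmse: float
    ccc: float
    n: int


def _check_binary_pair(truth: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    for name, arr in (("truth", truth), ("pred", pred)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary {{0, 1}}")
    return truth.astype(bool), pred.astype(bool)


def confusion_counts(truth: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    t, p = _check_binary_pair(truth, pred)
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def dice(truth: np.ndarray, pred: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); undefined when both masks are empty."""
    c = confusion_counts(truth, pred)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise DegenerateInputError("Dice undefined: both masks empty")
    return 2.0 * c.tp / denom


def sensitivity(truth: np.ndarray, pred: np.ndarray) -> float:
    """True-positive rate tp / (tp + fn); needs >= 1 true foreground pixel."""
    c = confusion_counts(truth, pred)
    if c.tp + c.fn == 0:
        raise DegenerateInputError("sensitivity undefined: truth has no foreground")
    return c.tp / (c.tp + c.fn)


def specificity(truth: np.ndarray, pred: np.ndarray) -> float:
    """True-negative rate tn / (tn + fp); needs >= 1 true background pixel."""
    c = confusion_counts(truth, pred)
    if c.tn + c.fp == 0:
        raise DegenerateInputError("specificity undefined: truth has no background")
    return c.tn / (c.tn + c.fp)


def _check_pair(truth: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth, dtype=np.float64).ravel()
    pred = np.asarray(pred, dtype=np.float64).ravel()
    if truth.size != pred.size:
        raise ValueError(f"length mismatch: {truth.size} vs {pred.size}")
    if truth.size == 0:
        raise ValueError("empty sequences")
    return truth, pred


def mae(truth: np.ndarray, pred: np.ndarray) -> float:
    t, p = _check_pair(truth, pred)
    return float(np.mean(np.abs(t - p)))


def rmse(truth: np.ndarray, pred: np.ndarray) -> float:
    t, p = _check_pair(truth, pred)
    return float(np.sqrt(np.mean((t - p) ** 2)))


def ccc(truth: np.ndarray, pred: np.ndarray) -> float:
    """Lin's concordance correlation coefficient with population moments.

    ccc = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2), in
    [-1, 1]; equals 1 iff y = x exactly. Requires both sequences to be
    non-constant.
    """
    x, y = _check_pair(truth, pred)
    if x.size < 2:
        raise ValueError("ccc needs length >= 2")
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        raise DegenerateInputError("ccc undefined for a constant sequence")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def regression_report(
    truth_months: np.ndarray, pred_months: np.ndarray, cohort: str = "all"
) -> RegressionEvalReport:
    t, p = _check_pair(truth_months, pred_months)
    return RegressionEvalReport(
        cohort=cohort, mae=mae(t, p), rmse=rmse(t, p), ccc=ccc(t, p), n=int(t.size)
    )
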