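"""Model evaluation: 3:1 time-ordered split, accuracy metrics, RPD grade.

The chemometric vocabulary: the *calibration set* trains the model, the
*prediction set* is the held-out evaluation set.  Samples are time
ordered (by drought period); the split interleaves every 4th sample of
the ordered list into the prediction set so both sets span all drought
levels.  Accuracy is summarized by Pearson R and RMSE on each set, a
cross-validated RMSECV on the calibration set, and the ratio of
performance to deviation RPD = SD(prediction-set reference) / RMSEP,
graded ``excellent`` (RPD >= 2), ``rough`` (1.4 <= RPD < 2) or
``unusable`` (RPD < 1.4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateDataError
from .regression import contiguous_folds

RPD_EXCELLENT = 2.0
RPD_ROUGH = 1.4


@dataclass
class SplitIndices:
    calibration: np.ndarray
    prediction: np.ndarray
    ratio: tuple[int, int] = (3, 1)

    def __post_init__(self) -> None:
        self.calibration = np.asarray(self.calibration, dtype=int)
        self.prediction = np.asarray(self.prediction, dtype=int)
        overlap = np.intersect1d(self.calibration, self.prediction)
        if overlap.size:
            raise ConfigurationError("calibration and prediction sets overlap")


def split_by_time(
    n_samples: int,
    periods: np.ndarray | None = None,
    ratio: tuple[int, int] = (3, 1),
    block: bool = False,
) -> SplitIndices:
    """Deterministic calibration/prediction split of time-ordered samples.

    Default (interleaved): with ratio ``(c, p)``, the last *p* positions
    of every ``c + p``-long cycle of the ordered sample list go to the
    prediction set — for 180 samples at 3:1 that is every 4th sample,
    giving 135 calibration and 45 prediction samples, with every drought
    period represented in both sets.  ``block=True`` instead assigns the
    trailing quarter of the time-course wholesale (the alternative
    reading of a 3:1 time-ranked split).
    """
    c, p = ratio
    if c < 1 or p < 1:
        raise ConfigurationError("ratio parts must be >= 1")
    cycle = c + p
    if n_samples < cycle:
        raise ConfigurationError(
            f"need at least {cycle} samples for a {c}:{p} split, got {n_samples}"
        )
    idx = np.arange(n_samples)
    if block:
        n_pred = n_samples // cycle * p
        pred = idx[n_samples - n_pred:]
    else:
        pred = idx[(idx % cycle) >= c]
    cal = np.setdiff1d(idx, pred)
    if periods is not None:
        periods = np.asarray(periods)
        if periods.size != n_samples:
            raise ConfigurationError("period labels do not match sample count")
    return SplitIndices(cal, pred, ratio)


def pearson_r(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ConfigurationError("need two equal-length vectors of >= 2 values")
    if y_true.std() == 0 or y_pred.std() == 0:
        raise DegenerateDataError("correlation undefined for zero-variance input")
    a = y_true - y_true.mean()
    b = y_pred - y_pred.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size != y_pred.size or y_true.size < 1:
        raise ConfigurationError("need two equal-length vectors")
    d = y_true - y_pred
    return float(np.sqrt(d @ d / d.size))


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """(Pearson R, RMSE) of a set of predictions."""
    return pearson_r(y_true, y_pred), rmse(y_true, y_pred)


def rpd(y_true_prediction_set: np.ndarray, rmsep: float) -> tuple[float, str]:
    """Ratio of performance to deviation and its grade.

    RPD is the sample SD (ddof = 1) of the prediction set's *reference*
    values divided by RMSEP; a perfect model (RMSEP = 0) grades
    ``excellent`` with infinite RPD.
    """
    y = np.asarray(y_true_prediction_set, dtype=float)
    if y.size < 2:
        raise ConfigurationError("RPD needs >= 2 reference values")
    sd = float(y.std(ddof=1))
    if sd == 0:
        raise DegenerateDataError("RPD undefined for zero-variance reference values")
    if rmsep < 0:
        raise ConfigurationError("RMSEP must be non-negative")
    value = np.inf if rmsep == 0 else sd / rmsep
    return float(value), grade_rpd(value)


def grade_rpd(value: float) -> str:
    if value >= RPD_EXCELLENT:
        return "excellent"
    if value >= RPD_ROUGH:
        return "rough"
    return "unusable"


def rmsecv(fit_predict, X: np.ndarray, y: np.ndarray, folds: int = 5) -> float:
    """Out-of-fold RMSE over contiguous time blocks.

    *fit_predict* is called as ``fit_predict(X_train, y_train, X_test)``
    and must refit the entire model specification — preprocessing
    statistics included — on the training block alone.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    sq = 0.0
    for test_idx in contiguous_folds(len(y), folds):
        train = np.setdiff1d(np.arange(len(y)), test_idx)
        if train.size < 2:
            raise ConfigurationError("fold too small to fit a model")
        yhat = np.asarray(fit_predict(X[train], y[train], X[test_idx]), dtype=float)
        resid = y[test_idx] - yhat
        sq += float(resid @ resid)
    return float(np.sqrt(sq / len(y)))


@dataclass
class EvalReport:
    """Accuracy summary for one pipeline configuration."""

    descriptor: str
    Rcal: float
    RMSEC: float
    RMSECV: float
    Rp: float
    RMSEP: float
    RPD: float
    rpd_grade: str = ""
    R2cal: float = field(default=np.nan)
    R2p: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if not self.rpd_grade:
            self.rpd_grade = grade_rpd(self.RPD)
        if np.isnan(self.R2cal):
            self.R2cal = self.Rcal**2
        if np.isnan(self.R2p):
            self.R2p = self.Rp**2

    def as_row(self) -> dict:
        return {
            "Modeling method": self.descriptor,
            "Rcal": self.Rcal,
            "RMSEC": self.RMSEC,
            "RMSECV": self.RMSECV,
            "Rp": self.Rp,
            "RMSEP": self.RMSEP,
            "RPD": self.RPD,
            "grade": self.rpd_grade,
        }


def evaluate(
    descriptor: str,
    y_cal: np.ndarray,
    yhat_cal: np.ndarray,
    y_pred: np.ndarray,
    yhat_pred: np.ndarray,
    rmsecv_value: float = np.nan,
) -> EvalReport:
    """Assemble an :class:`EvalReport` from true/predicted pairs."""
    r_cal, rmsec = metrics(y_cal, yhat_cal)
    r_p, rmsep = metrics(y_pred, yhat_pred)
    rpd_value, grade = rpd(y_pred, rmsep)
    return EvalReport(descriptor, r_cal, rmsec, rmsecv_value, r_p, rmsep,
                      rpd_value, grade)
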