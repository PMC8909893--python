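"""Model evaluation: R², RMSE, RPD, limit of detection, and report rows.

Metrics follow the chemometric conventions of the study design they
implement:

* ``R²`` is the standard coefficient of determination,
  ``1 - Σ(y_p - y_m)² / Σ(y_m - ȳ_m)²``.  A variant with the predicted
  values in the denominator exists in parts of the literature; it can exceed
  1 and contradicts the definition's own legend, so it is available only
  behind ``printed_denominator=True``.
* ``RMSE`` uses the plain ``1/m`` denominator.
* ``RPD`` divides the standard deviation of the *predicted* values (unbiased
  ``m - 1`` SD) by the split's RMSE, exactly as specified here; the more
  common ``SD(measured)`` numerator is available via ``use_measured_sd``.
  RPD ≥ 1.4 labels a model "good".
* ``LOD = 3 · RMSE_cal / slope_cal`` where the calibration RMSE comes from
  the training split and the slope is the OLS slope of predicted on measured
  in training — the conventional reading of "slope of the calibration".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "PredictionSet",
    "r_squared",
    "rmse",
    "rpd",
    "calibration_slope",
    "lod",
    "EvaluationReport",
    "evaluate",
    "RPD_GOOD_THRESHOLD",
]

RPD_GOOD_THRESHOLD = 1.4


@dataclass
class PredictionSet:
    """Measured and predicted responses for one split."""

    y_measured: np.ndarray
    y_predicted: np.ndarray
    split: str = "training"

    def __post_init__(self) -> None:
        self.y_measured = np.asarray(self.y_measured, dtype=float).ravel()
        self.y_predicted = np.asarray(self.y_predicted, dtype=float).ravel()
        if self.y_measured.size != self.y_predicted.size:
            raise ValueError("measured and predicted vectors differ in length")
        if self.y_measured.size < 2:
            raise ValueError("a prediction set needs at least 2 samples")

    @property
    def m(self) -> int:
        return self.y_measured.size

    @property
    def y_bar(self) -> float:
        return float(self.y_measured.mean())

    @property
    def sd_predicted(self) -> float:
        return float(self.y_predicted.std(ddof=1))


def _as_pred(pred, y_predicted=None) -> PredictionSet:
    if isinstance(pred, PredictionSet):
        return pred
    return PredictionSet(pred, y_predicted)


def r_squared(pred, y_predicted=None, printed_denominator: bool = False) -> float:
    """Coefficient of determination of the predictions.

    Accepts a :class:`PredictionSet` or ``(y_measured, y_predicted)``.
    """
    p = _as_pred(pred, y_predicted)
    ss_res = float(np.sum((p.y_predicted - p.y_measured) ** 2))
    if printed_denominator:
        ss_tot = float(np.sum((p.y_predicted - p.y_bar) ** 2))
    else:
        ss_tot = float(np.sum((p.y_measured - p.y_bar) ** 2))
    if ss_tot == 0:
        raise ValueError("response has zero variance; R² undefined")
    return 1.0 - ss_res / ss_tot


def rmse(pred, y_predicted=None) -> float:
    """Root mean square error with denominator ``m`` (not ``m - 1``)."""
    p = _as_pred(pred, y_predicted)
    return float(np.sqrt(np.mean((p.y_predicted - p.y_measured) ** 2)))


def rpd(pred, y_predicted=None, use_measured_sd: bool = False) -> float:
    """Ratio of performance to deviation: ``SD / RMSE`` for the split.

    By default the SD is that of the predicted values (``m - 1``
    denominator).  A zero RMSE makes the ratio infinite and raises.
    """
    p = _as_pred(pred, y_predicted)
    e = rmse(p)
    if e == 0:
        raise ValueError("RMSE is zero; RPD is infinite")
    sd = float(p.y_measured.std(ddof=1)) if use_measured_sd else p.sd_predicted
    return sd / e


def calibration_slope(y_measured, y_predicted) -> float:
    """OLS slope of predicted on measured (the calibration line)."""
    y_m = np.asarray(y_measured, dtype=float).ravel()
    y_p = np.asarray(y_predicted, dtype=float).ravel()
    xm = y_m - y_m.mean()
    sxx = float(xm @ xm)
    if sxx == 0:
        raise ValueError("measured values are constant; slope undefined")
    return float(xm @ (y_p - y_p.mean())) / sxx


def lod(rmse_cal: float, slope_cal: float) -> float:
    """Limit of detection: ``3 · RMSE_cal / slope_cal`` (ratio units)."""
    if slope_cal == 0:
        raise ValueError("calibration slope is zero; LOD undefined")
    return 3.0 * rmse_cal / slope_cal


@dataclass
class EvaluationReport:
    """One row of the model-grid table: all metrics plus provenance."""

    r2_train: float
    r2_test: float
    rmse_train: float
    rmse_test: float
    rpd_train: float
    rpd_test: float
    lod: float
    quality: str = ""
    treatment: str = ""
    model_type: str = ""
    hyperparameter: float | int | None = None
    selection_method: str | None = None
    n_bands: int | None = None

    def __post_init__(self) -> None:
        if not self.quality:
            self.quality = "good" if self.rpd_test >= RPD_GOOD_THRESHOLD else "poor"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "EvaluationReport":
        return cls.from_dict(json.loads(s))


def evaluate(model, X_train, y_train, X_test, y_test, *, treatment: str = "",
             model_type: str = "", hyperparameter=None, selection_method=None,
             n_bands=None) -> EvaluationReport:
    """Evaluate a fitted model on both splits and assemble the report row.

    A perfect model has zero RMSE on a split; its RPD is reported as
    ``inf`` (rather than raising) so the degenerate case still yields a
    complete row, and its LOD is exactly 0.
    """
    from .regression import predict  # local import to avoid a cycle

    train = PredictionSet(y_train, predict(model, X_train), split="training")
    test = PredictionSet(y_test, predict(model, X_test), split="testing")
    rmse_tr, rmse_te = rmse(train), rmse(test)
    rpd_tr = rpd(train) if rmse_tr > 0 else math.inf
    rpd_te = rpd(test) if rmse_te > 0 else math.inf
    slope = calibration_slope(train.y_measured, train.y_predicted)
    if n_bands is None:
        n_bands = int(model.coef.size)
    return EvaluationReport(
        r2_train=r_squared(train), r2_test=r_squared(test),
        rmse_train=rmse_tr, rmse_test=rmse_te,
        rpd_train=rpd_tr, rpd_test=rpd_te,
        lod=lod(rmse_tr, slope),
        treatment=treatment, model_type=model_type,
        hyperparameter=hyperparameter, selection_method=selection_method,
        n_bands=n_bands,
    )
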