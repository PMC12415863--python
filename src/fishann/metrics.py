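"""Prediction-quality metrics: RMSE, MAPE with interpretation bands, and two
coefficient-of-determination variants.

Two R-squared variants are computed side by side:

* ``r2_conventional`` — the textbook coefficient of determination,
  1 - SS_res / SS_tot with SS_tot centered on the mean of the actuals.
* ``r2_prednorm`` — a variant in which the residual sum of squares is
  normalized by the raw sum of squared *predictions*,
  1 - sum((a - p)^2) / sum(p^2).  Some applied ANN reports print this
  formula; it saturates near 1 whenever predictions are far from zero, so it
  cannot discriminate between good models.  Both are reported; model
  selection in :mod:`fishann.pipeline` uses the conventional variant.

MAPE interpretation bands (percent): <=10 high accuracy, (10, 20] good,
(20, 50) acceptable, >=50 misleading.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MapeBand",
    "EvalMetrics",
    "rmse",
    "mape",
    "classify_mape",
    "r2_conventional",
    "r2_prednorm",
    "evaluate",
]


class MapeBand(str, enum.Enum):
    HIGH_ACCURACY = "high_accuracy"
    GOOD = "good"
    ACCEPTABLE = "acceptable"
    MISLEADING = "misleading"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _check_pair(actual, predicted):
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("actual and predicted must be 1-D vectors of equal length")
    if a.size == 0:
        raise ValueError("empty vectors")
    return a, p


def rmse(actual, predicted) -> float:
    """Root mean square error, sqrt(sum((a-p)^2)/N)."""
    a, p = _check_pair(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def mape(actual, predicted) -> float:
    """Mean absolute percentage error, (100/N) * sum(|a-p| / |a|).

    Undefined when any actual value is zero.
    """
    a, p = _check_pair(actual, predicted)
    if np.any(a == 0):
        raise ValueError("MAPE undefined: actual contains zero")
    return float(np.mean(np.abs((a - p) / a)) * 100.0)


def classify_mape(m: float) -> MapeBand:
    """Assign a MAPE value (percent) to its interpretation band.

    The bands partition [0, inf): [0, 10] high accuracy, (10, 20] good,
    (20, 50) acceptable, [50, inf) misleading.  The boundary at exactly 50
    is labeled misleading (conservative choice for the open point).
    """
    m = float(m)
    if m < 0:
        raise ValueError("MAPE cannot be negative")
    if m <= 10:
        return MapeBand.HIGH_ACCURACY
    if m <= 20:
        return MapeBand.GOOD
    if m < 50:
        return MapeBand.ACCEPTABLE
    return MapeBand.MISLEADING


def r2_prednorm(actual, predicted) -> float:
    """R-squared with the residual sum normalized by sum(predicted^2).

    ``1 - sum((a-p)^2) / sum(p^2)``.  Undefined when all predictions are
    zero.  See the module docstring for why this variant saturates.
    """
    a, p = _check_pair(actual, predicted)
    denom = float(np.sum(p**2))
    if denom <= 0:
        raise ValueError("r2_prednorm undefined: all predictions are zero")
    return float(1.0 - np.sum((a - p) ** 2) / denom)


def r2_conventional(actual, predicted) -> float:
    """Conventional coefficient of determination.

    ``1 - sum((a-p)^2) / sum((a - mean(a))^2)``.  Undefined for constant
    actuals (requires at least two distinct values).
    """
    a, p = _check_pair(actual, predicted)
    if a.size < 2:
        raise ValueError("r2_conventional needs at least two observations")
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("r2_conventional undefined: actual is constant")
    return float(1.0 - np.sum((a - p) ** 2) / ss_tot)


@dataclass(frozen=True)
class EvalMetrics:
    """All four metrics for one prediction set, plus the MAPE band."""

    rmse: float
    mape: float
    mape_band: MapeBand
    r2_prednorm: float
    r2_conventional: float
    n: int


def evaluate(actual, predicted) -> EvalMetrics:
    """Compute the full metric set for one (actual, predicted) pair."""
    a, p = _check_pair(actual, predicted)
    m = mape(a, p)
    return EvalMetrics(
        rmse=rmse(a, p),
        mape=m,
        mape_band=classify_mape(m),
        r2_prednorm=r2_prednorm(a, p),
        r2_conventional=r2_conventional(a, p),
        n=int(a.size),
    )
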