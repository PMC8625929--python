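"""Semi-parametric trend + seasonal adjustment for monthly series.

A series Y_t is decomposed as Y_t = mu_t + mu_{t,month} + f(X_t): a linear
long-term trend fit by ordinary least squares on the time index, per-month
seasonal means of the detrended series, and a residual left for any
probabilistic regressor.  Trend and seasonal components are estimated from
training rows only; ``retrend`` is the exact inverse of ``detrend``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class TrendModel:
    intercept: float = 0.0
    slope: float = 0.0
    seasonal: np.ndarray = field(default_factory=lambda: np.zeros(12))
    fitted: bool = False
    residual_model: Optional[object] = None

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "slope": self.slope,
                "seasonal": np.asarray(self.seasonal).tolist()}

    @staticmethod
    def from_dict(d: dict) -> "TrendModel":
        return TrendModel(intercept=d["intercept"], slope=d["slope"],
                          seasonal=np.asarray(d["seasonal"], dtype=float),
                          fitted=True)


def fit_trend_seasonal(times, y, month_of=None) -> TrendModel:
    """OLS linear trend on the time index, then per-month seasonal means.

    Months absent from the training rows keep a seasonal mean of zero (a
    warning is emitted).
    """
    times = np.asarray(times, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if times.size != y.size:
        raise ValueError("times and y lengths differ")
    if times.size < 24:
        raise ValueError("need at least 24 points")
    month_of = (np.asarray(times).astype(int) % 12 if month_of is None
                else np.asarray(month_of, dtype=int))
    if np.unique(month_of).size < 2:
        raise ValueError("need at least 2 distinct calendar months")
    if np.ptp(times) == 0:
        raise np.linalg.LinAlgError("constant time index: singular design")
    D = np.column_stack([np.ones_like(times), times])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    detrended = y - D @ beta
    seasonal = np.zeros(12)
    missing = []
    for m in range(12):
        sel = month_of == m
        if sel.any():
            seasonal[m] = detrended[sel].mean()
        else:
            missing.append(m)
    if missing:
        warnings.warn(f"months {missing} absent from training rows; "
                      "their seasonal means are set to 0")
    return TrendModel(intercept=float(beta[0]), slope=float(beta[1]),
                      seasonal=seasonal, fitted=True)


def _components(model: TrendModel, times, month_of):
    times = np.asarray(times, dtype=float).ravel()
    month_of = (np.asarray(times).astype(int) % 12 if month_of is None
                else np.asarray(month_of, dtype=int))
    return model.intercept + model.slope * times \
        + np.asarray(model.seasonal)[month_of]


def detrend(model: TrendModel, times, y, month_of=None) -> np.ndarray:
    """y minus the fitted trend and seasonal components."""
    if not model.fitted:
        raise RuntimeError("TrendModel is not fitted")
    return np.asarray(y, dtype=float).ravel() \
        - _components(model, times, month_of)


def retrend(model: TrendModel, times, predictions, month_of=None) -> np.ndarray:
    """Exact inverse of :func:`detrend`."""
    if not model.fitted:
        raise RuntimeError("TrendModel is not fitted")
    return np.asarray(predictions, dtype=float).ravel() \
        + _components(model, times, month_of)
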