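"""Regression metrics, uncertainty summaries and relative efficiency.

Relative efficiency RE_W = TestMSE / TestMSE_W compares a model trained on
raw data with the same model trained on Winsorized data: RE_W = 1 means no
change and RE_W > 1 means Winsorization improved the test MSE.  The
epistemic-uncertainty summary is the mean over test points of the posterior
predictive standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Dict, Optional, Sequence

import numpy as np
from sklearn.metrics import (mean_absolute_error, mean_squared_error,
                             median_absolute_error, r2_score)

from .prediction import PosteriorPrediction


class UndefinedR2Warning(UserWarning):
    """Test targets are constant, so the coefficient of determination is
    undefined; other metrics are still reported."""


@dataclass
class MetricsReport:
    mse: float
    mae: float
    median_ae: float
    r2: float                    # may be negative; NaN when SST = 0
    mean_pred_std: float
    sup_abs_error: float
    n_test: int
    condition: str = "untouched"
    winsorized: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def regression_metrics(y, pred: PosteriorPrediction,
                       condition: str = "untouched",
                       winsorized: bool = False) -> MetricsReport:
    """MSE, MAE, median AE, R^2, mean predictive sd and sup absolute error."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size != pred.mean.size:
        raise ValueError("y and prediction lengths differ")
    if y.size < 2:
        raise ValueError("need at least 2 test points")
    if np.ptp(y) == 0:
        warnings.warn("constant test targets: R^2 is undefined",
                      UndefinedR2Warning)
        r2 = np.nan
    else:
        r2 = float(r2_score(y, pred.mean))
    err = y - pred.mean
    return MetricsReport(
        mse=float(mean_squared_error(y, pred.mean)),
        mae=float(mean_absolute_error(y, pred.mean)),
        median_ae=float(median_absolute_error(y, pred.mean)),
        r2=r2,
        mean_pred_std=float(np.mean(pred.std)),
        sup_abs_error=float(np.max(np.abs(err))),
        n_test=int(y.size),
        condition=condition,
        winsorized=winsorized,
    )


def relative_efficiency(mse: float, mse_w: float) -> float:
    """RE_W = mse / mse_w; > 1 means Winsorization helped."""
    if mse_w <= 0:
        raise ValueError("mse_w must be positive")
    return float(mse) / float(mse_w)


def select_optimal_limit(results: Dict[float, Sequence[float]]) -> float:
    """The alpha minimizing the seed-mean Winsorized test MSE.

    Ties go to the smaller alpha (less information loss).
    """
    if not results:
        raise ValueError("empty results map")
    means = {}
    for alpha, values in results.items():
        values = [v for v in np.asarray(list(values), dtype=float)
                  if np.isfinite(v)]
        if not values:
            raise ValueError(f"no finite values for alpha={alpha}")
        means[float(alpha)] = float(np.mean(values))
    best = min(means.values())
    return min(a for a, m in means.items() if m <= best + 1e-12)
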