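"""Two-sided order-statistic Winsorization of vectors and dataset variables.

Winsorization at limit alpha replaces the lowest alpha-fraction of a
variable's values with the nearest retained low order statistic and the
highest alpha-fraction with the nearest retained high order statistic: with
alpha * n integral the smallest floor(alpha*n) values become the
(floor(alpha*n)+1)-th order statistic and symmetrically at the top (the
classical n=100, alpha=0.05 case replaces the smallest five values with the
sixth-lowest and the largest five with the 95th-lowest).  For non-integral
alpha * n the replacement bounds are linearly interpolated between adjacent
order statistics, which is continuous in alpha and coincides with the
order-statistic rule at integral alpha * n.

On datasets, replacement quantiles are estimated from designated reference
splits (train and validation pooled, by default) and applied by clipping to
designated splits; test rows are never used for estimation and, by default,
never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .datasets import Dataset

WINSOR_VARIABLES = ("target", "features", "both", "none")

#: limit grid used throughout the benchmarking protocol (0 to 25 percentile)
DEFAULT_ALPHA_GRID = (0.0, 0.01, 0.05, 0.10, 0.15, 0.20, 0.25)


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not (0.0 <= alpha < 0.5):
        raise ValueError("alpha must lie in [0, 0.5)")
    return alpha


def winsor_bounds(x: np.ndarray, alpha: float) -> Tuple[float, float]:
    """Lower/upper replacement values for a sample at limit alpha."""
    alpha = _check_alpha(alpha)
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    n = x.size
    xs = np.sort(x)
    # continuous 0-based order-statistic positions: at integral alpha*n = k
    # the lower bound is the (k+1)-th order statistic, i.e. 0-based index k,
    # and the upper bound the (n-k)-th order statistic.
    pos_lo = min(alpha * n, n - 1.0)
    pos_hi = max((1.0 - alpha) * n - 1.0, 0.0)
    idx = np.arange(n, dtype=float)
    lo = float(np.interp(pos_lo, idx, xs))
    hi = float(np.interp(pos_hi, idx, xs))
    return lo, hi


def winsorize_vector(x: np.ndarray, alpha: float) -> np.ndarray:
    """Winsorize a vector at limit alpha; element order is preserved."""
    x = np.asarray(x, dtype=float)
    lo, hi = winsor_bounds(x, alpha)
    return np.clip(x, lo, hi)


@dataclass
class WinsorSpec:
    """A fitted Winsorization treatment: limit, variables and bounds.

    ``lower``/``upper`` map variable names (feature names plus ``"target"``)
    to the replacement values estimated on the reference splits, so the
    treatment can be re-applied verbatim to new rows.
    """

    alpha: float
    variables: str
    reference_subsets: tuple = ("train", "val")
    lower: Dict[str, float] = field(default_factory=dict)
    upper: Dict[str, float] = field(default_factory=dict)
    quantile_method: str = "order-statistic-linear"

    def __post_init__(self):
        _check_alpha(self.alpha)
        if self.variables not in WINSOR_VARIABLES:
            raise ValueError(f"unknown variables tag {self.variables!r}")
        for k in self.lower:
            if self.lower[k] > self.upper[k]:
                raise ValueError("lower bound above upper bound")

    def apply(self, ds: Dataset, subsets=("train", "val")) -> Dataset:
        """Clip the designated splits of ``ds`` to the fitted bounds."""
        out = ds.copy()
        m = ds.mask(*subsets)
        if self.variables in ("target", "both") and "target" in self.lower:
            out.target[m] = np.clip(ds.target[m], self.lower["target"],
                                    self.upper["target"])
        if self.variables in ("features", "both"):
            for j, name in enumerate(ds.feature_names):
                if name in self.lower:
                    out.features[m, j] = np.clip(
                        ds.features[m, j], self.lower[name], self.upper[name])
        return out

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "variables": self.variables,
                "reference_subsets": list(self.reference_subsets),
                "lower": dict(self.lower), "upper": dict(self.upper),
                "quantile_method": self.quantile_method}

    @staticmethod
    def from_dict(d: dict) -> "WinsorSpec":
        return WinsorSpec(alpha=d["alpha"], variables=d["variables"],
                          reference_subsets=tuple(d["reference_subsets"]),
                          lower=dict(d["lower"]), upper=dict(d["upper"]),
                          quantile_method=d.get("quantile_method",
                                                "order-statistic-linear"))


def variables_for_site(site: str) -> str:
    """Which variables to Winsorize when studying a given noise site.

    The treatment targets the contamination: target-site noise is countered
    by Winsorizing the target, feature-site by Winsorizing the features,
    both by both; in the noise-free condition both are clipped.
    """
    return {"none": "both", "target": "target",
            "features": "features", "both": "both"}[site]


def winsorize_dataset(ds: Dataset, alpha: float, variables: str = "both",
                      apply_subsets=("train", "val"),
                      reference_subsets=("train", "val")
                      ) -> Tuple[Dataset, WinsorSpec]:
    """Fit replacement quantiles on reference splits and clip apply splits.

    Returns the treated Dataset and the fitted :class:`WinsorSpec`.  At
    ``alpha = 0`` the data are unchanged and the spec records the identity
    bounds (per-variable min/max of the reference rows).
    """
    alpha = _check_alpha(alpha)
    if variables not in WINSOR_VARIABLES:
        raise ValueError(f"unknown variables tag {variables!r}")
    spec = WinsorSpec(alpha=alpha, variables=variables,
                      reference_subsets=tuple(reference_subsets))
    ref = ds.mask(*reference_subsets)
    if not ref.any():
        raise ValueError("no rows in reference subsets")
    if variables in ("target", "both"):
        lo, hi = winsor_bounds(ds.target[ref], alpha)
        spec.lower["target"], spec.upper["target"] = lo, hi
    if variables in ("features", "both"):
        for j, name in enumerate(ds.feature_names):
            lo, hi = winsor_bounds(ds.features[ref, j], alpha)
            spec.lower[name], spec.upper[name] = lo, hi
    return spec.apply(ds, subsets=apply_subsets), spec
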