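"""Seeded synthetic regression datasets for robustness benchmarking.

Five archetypes emulate the statistical structure of common applied
regression problems:

* ``crop`` — county-level crop yield driven by daily weather curves
  (365 tmax + 365 tmin + 365 precipitation features, longitude/latitude and
  their cosine/sine transforms; 1101 features in total);
* ``tabular`` — housing-style regression with a handful of features,
  optionally with a right-skewed target (burned-area style);
* ``series`` — a monthly series with a linear trend and 12-month seasonality;
* ``highdim`` — high-dimensional, low-sample expression-style data
  (default 238 features, 4 latent groups);
* ``multimodal`` — a conditional Gaussian-mixture response for mixture
  density network component-recovery checks.

Every generator is a pure function of its arguments, produces only finite
values, and records its planted ground-truth parameters in
``Dataset.provenance`` so parameter-recovery tests need no re-derivation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SPLIT_LABELS = ("train", "val", "test")
ARCHETYPES = ("crop", "tabular", "heavy_tail", "series", "highdim",
              "multimodal", "custom")

#: crop-archetype feature layout: 3 daily weather curves + lon/lat + trig
CROP_N_FEATURES = 365 + 365 + 365 + 2 + 4


@dataclass
class Dataset:
    """A feature matrix with target, per-row split labels and provenance."""

    features: np.ndarray          # (n, p)
    target: np.ndarray            # (n,)
    split: np.ndarray             # (n,) labels in SPLIT_LABELS
    archetype: str
    feature_names: list
    seed: int
    time_index: Optional[np.ndarray] = None   # series archetype only
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.target = np.asarray(self.target, dtype=float)
        self.split = np.asarray(self.split)
        if self.features.shape[0] != self.target.shape[0]:
            raise ValueError("features and target row counts differ")
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must equal column count")
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def mask(self, *labels: str) -> np.ndarray:
        return np.isin(self.split, labels)

    def rows(self, *labels: str) -> tuple:
        m = self.mask(*labels)
        return self.features[m], self.target[m]

    def copy(self) -> "Dataset":
        return Dataset(self.features.copy(), self.target.copy(),
                       self.split.copy(), self.archetype,
                       list(self.feature_names), self.seed,
                       None if self.time_index is None else self.time_index.copy(),
                       dict(self.provenance))

    # -- serialization --------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write one row per observation plus a JSON provenance sidecar."""
        path = Path(path)
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df["target"] = self.target
        df["split"] = self.split
        if self.time_index is not None:
            df["time_index"] = self.time_index
        df.to_csv(path, index=False)
        sidecar = {"archetype": self.archetype, "seed": self.seed,
                   "provenance": _jsonable(self.provenance)}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @staticmethod
    def from_csv(path, target_column: str = "target",
                 archetype: str = "custom") -> "Dataset":
        path = Path(path)
        df = pd.read_csv(path)
        split = df.pop("split").to_numpy() if "split" in df else \
            np.full(len(df), "train")
        time_index = df.pop("time_index").to_numpy() if "time_index" in df \
            else None
        y = df.pop(target_column).to_numpy(dtype=float)
        seed, prov = 0, {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            archetype = meta.get("archetype", archetype)
            seed = meta.get("seed", 0)
            prov = meta.get("provenance", {})
        return Dataset(df.to_numpy(dtype=float), y, split, archetype,
                       list(df.columns), seed, time_index, prov)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _check_finite(ds: Dataset) -> Dataset:
    if not (np.all(np.isfinite(ds.features)) and np.all(np.isfinite(ds.target))):
        raise RuntimeError("generator produced non-finite values")
    return ds


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_tabular_regression(n: int, p: int, noise_sd: float = 0.5,
                            skew_target: bool = False, seed: int = 0) -> Dataset:
    """Smooth nonlinear regression surface with Gaussian noise.

    The mean function is linear-plus-sinusoid-plus-interaction with planted
    coefficients recorded in provenance; ``planted_tabular_mean`` evaluates
    it exactly.  With ``skew_target`` the noisy response is pushed through an
    amplified softplus, which makes the sample skewness positive
    (burned-area-style heavy right tail).
    """
    if n < 30 or p < 1:
        raise ValueError("need n >= 30 and p >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(scale=0.7, size=p)
    amp_sin, amp_int = 1.2, 0.5
    prov = {"beta": beta, "amp_sin": amp_sin, "amp_int": amp_int,
            "noise_sd": noise_sd, "skew_target": skew_target}
    y = planted_tabular_mean(X, prov) + noise_sd * rng.normal(size=n)
    if skew_target:
        z = (y - y.mean()) / max(y.std(), 1e-12)
        y = np.log1p(np.exp(np.clip(2.0 * z, -30, 30)))  # right-skewed
    archetype = "heavy_tail" if skew_target else "tabular"
    names = [f"x{j}" for j in range(p)]
    return _check_finite(Dataset(X, y, np.full(n, "train"), archetype,
                                 names, seed, provenance=prov))


def planted_tabular_mean(X: np.ndarray, prov: dict) -> np.ndarray:
    """Evaluate the tabular generator's exact mean function."""
    beta = np.asarray(prov["beta"], dtype=float)
    j2 = 1 if X.shape[1] > 1 else 0
    return (X @ beta + prov["amp_sin"] * np.sin(X[:, 0])
            + prov["amp_int"] * X[:, 0] * X[:, j2])


def make_crop_archetype(n_sites: int, n_years: int, seed: int = 0) -> Dataset:
    """Site-year crop-yield rows with daily weather curves (p = 1101).

    Each row is one site in one year.  Daily maximum temperature follows a
    seasonal sinusoid whose level decreases with latitude; minimum
    temperature sits a noisy offset below it; precipitation is nonnegative
    with a summer peak.  Yield is a latitude baseline plus a growing-season
    mean-tmax effect and a negative harvest-window precipitation effect —
    wet harvests hurt yield — plus Gaussian noise.  The sufficient
    statistics and their planted coefficients are in provenance.
    """
    n = n_sites * n_years
    if n < 30:
        raise ValueError("need n_sites * n_years >= 30")
    rng = np.random.default_rng(seed)
    lon = rng.uniform(-97.0, -87.0, size=n_sites)
    lat = rng.uniform(37.0, 49.0, size=n_sites)
    days = np.arange(365)
    season = -np.cos(2 * np.pi * (days + 10) / 365)       # peak mid-July

    # planted coefficients on the sufficient statistics
    coef = {"intercept": 4.0, "lat": -0.25, "gs_tmax": 0.35,
            "harvest_prcp": -0.8, "noise_sd": 0.5,
            "gs_window": [120, 240], "harvest_window": [240, 300]}

    rows_tmax = np.empty((n, 365))
    rows_tmin = np.empty((n, 365))
    rows_prcp = np.empty((n, 365))
    site_ix = np.repeat(np.arange(n_sites), n_years)
    for i in range(n):
        s = site_ix[i]
        level = 17.0 - 0.6 * (lat[s] - 43.0) + rng.normal(scale=1.0)
        tmax = level + 13.0 * season + rng.normal(scale=2.0, size=365)
        tmin = tmax - (8.0 + rng.normal(scale=1.0)) \
            + rng.normal(scale=1.5, size=365)
        wet = 2.5 + 1.5 * np.clip(season, 0, None)
        prcp = rng.gamma(shape=1.2, scale=wet / 1.2, size=365)
        rows_tmax[i], rows_tmin[i], rows_prcp[i] = tmax, tmin, prcp

    lon_r, lat_r = lon[site_ix], lat[site_ix]
    gs0, gs1 = coef["gs_window"]
    h0, h1 = coef["harvest_window"]
    gs_tmax = rows_tmax[:, gs0:gs1].mean(axis=1)
    harvest_prcp = rows_prcp[:, h0:h1].mean(axis=1)
    y = (coef["intercept"] + coef["lat"] * (lat_r - 43.0)
         + coef["gs_tmax"] * (gs_tmax - 20.0)
         + coef["harvest_prcp"] * (harvest_prcp - 3.0)
         + rng.normal(scale=coef["noise_sd"], size=n))

    X = np.hstack([rows_tmax, rows_tmin, rows_prcp,
                   lon_r[:, None], lat_r[:, None],
                   np.cos(lon_r)[:, None], np.sin(lon_r)[:, None],
                   np.cos(lat_r)[:, None], np.sin(lat_r)[:, None]])
    names = ([f"tmax_{d}" for d in days] + [f"tmin_{d}" for d in days]
             + [f"prcp_{d}" for d in days] + ["lon", "lat",
                "cos_lon", "sin_lon", "cos_lat", "sin_lat"])
    assert X.shape[1] == CROP_N_FEATURES
    return _check_finite(Dataset(X, y, np.full(n, "train"), "crop", names,
                                 seed, provenance={"coef": coef}))


def crop_sufficient_statistics(ds: Dataset) -> np.ndarray:
    """(lat-43, gs-mean-tmax-20, harvest-mean-prcp-3) design for recovery."""
    coef = ds.provenance["coef"]
    gs0, gs1 = coef["gs_window"]
    h0, h1 = coef["harvest_window"]
    names = ds.feature_names
    tmax = ds.features[:, [names.index(f"tmax_{d}") for d in range(gs0, gs1)]]
    prcp = ds.features[:, [names.index(f"prcp_{d}") for d in range(h0, h1)]]
    lat = ds.features[:, names.index("lat")]
    return np.column_stack([lat - 43.0, tmax.mean(axis=1) - 20.0,
                            prcp.mean(axis=1) - 3.0])


def make_trend_seasonal_series(n_months: int, slope: float = 0.05,
                               seasonal_amps: Sequence[float] = None,
                               noise_sd: float = 0.3, seed: int = 0,
                               intercept: float = 10.0,
                               nonlinear_amp: float = 0.0) -> Dataset:
    """Monthly series: intercept + slope*t + 12-month seasonal + noise.

    The seasonal block (and any smooth nonlinear residual, off by default)
    is orthogonalized against the (1, t) design at generation time, so an
    ordinary-least-squares trend fit on the noiseless series recovers the
    slope exactly; the orthogonalized per-month effects are recorded in
    provenance as ``seasonal_effective``.
    """
    if n_months < 36:
        raise ValueError("need n_months >= 36")
    if seasonal_amps is None:
        seasonal_amps = 2.0 * np.sin(2 * np.pi * np.arange(12) / 12)
    seasonal_amps = np.asarray(seasonal_amps, dtype=float)
    if seasonal_amps.shape != (12,):
        raise ValueError("seasonal_amps must have 12 entries")
    rng = np.random.default_rng(seed)
    t = np.arange(n_months)
    month = t % 12
    # Adjust the 12 month effects so the seasonal block, viewed as a
    # sequence in t, is orthogonal to span{1, t} while remaining a pure
    # function of the calendar month: remove its weighted projection onto
    # (1, mean-time-per-month).  An OLS trend fit followed by per-month
    # means then recovers slope and seasonal effects exactly at zero noise.
    counts = np.bincount(month, minlength=12).astype(float)
    tau = np.array([t[month == m].mean() for m in range(12)])
    wsqrt = np.sqrt(counts)
    B = np.column_stack([np.ones(12), tau]) * wsqrt[:, None]
    coef_proj = np.linalg.lstsq(B, seasonal_amps * wsqrt, rcond=None)[0]
    eff = seasonal_amps - coef_proj[0] - coef_proj[1] * tau
    sblock = eff[month]
    if nonlinear_amp:
        extra = nonlinear_amp * np.sin(2 * np.pi * t / 97.0)
        D = np.column_stack([np.ones(n_months), t])
        sblock = sblock + extra \
            - D @ np.linalg.lstsq(D, extra, rcond=None)[0]
    y = intercept + slope * t + sblock + noise_sd * rng.normal(size=n_months)
    X = np.column_stack([t.astype(float),
                         np.sin(2 * np.pi * t / 12),
                         np.cos(2 * np.pi * t / 12)])
    prov = {"slope": slope, "intercept": intercept,
            "seasonal_amps": seasonal_amps, "seasonal_effective": eff,
            "noise_sd": noise_sd}
    return _check_finite(Dataset(X, y, np.full(n_months, "train"), "series",
                                 ["t", "sin_12", "cos_12"], seed,
                                 time_index=t, provenance=prov))


def make_highdim_lowsample(n: int = 300, p: int = 238,
                           k_informative: int = 10, seed: int = 0) -> Dataset:
    """Expression-style data: 4 latent groups, block-correlated features.

    The target depends only on ``k_informative`` seeded columns.
    """
    if k_informative > p:
        raise ValueError("k_informative must be <= p")
    if n < 30 or p < 1 or k_informative < 1:
        raise ValueError("need n >= 30, p >= 1, k_informative >= 1")
    rng = np.random.default_rng(seed)
    groups = rng.integers(0, 4, size=n)
    centroids = rng.normal(scale=1.0, size=(4, p))
    n_blocks = max(1, p // 30)
    block_of = rng.integers(0, n_blocks, size=p)
    factors = rng.normal(size=(n, n_blocks))
    X = centroids[groups] + 0.6 * factors[:, block_of] \
        + 0.8 * rng.normal(size=(n, p))
    informative = rng.choice(p, size=k_informative, replace=False)
    beta = rng.normal(scale=1.0, size=k_informative)
    y = X[:, informative] @ beta + 0.5 * rng.normal(size=n)
    prov = {"informative": informative, "beta": beta, "groups": groups,
            "noise_sd": 0.5}
    return _check_finite(Dataset(X, y, np.full(n, "train"), "highdim",
                                 [f"g{j}" for j in range(p)], seed,
                                 provenance=prov))


def make_multimodal_regression(n: int, n_modes: int = 2,
                               seed: int = 0) -> Dataset:
    """Conditional n-mode Gaussian-mixture response on a scalar input.

    At any fixed x the response density is a mixture of ``n_modes``
    well-separated Gaussians centred symmetrically about a shared smooth
    base curve (an odd function, so at x = 0 the mixture is mean-zero).
    """
    if n_modes < 2:
        raise ValueError("need n_modes >= 2")
    if n < 30:
        raise ValueError("need n >= 30")
    rng = np.random.default_rng(seed)
    x = rng.uniform(-3, 3, size=n)
    offsets = np.linspace(-2.0, 2.0, n_modes) * (n_modes / 2.0)
    comp = rng.integers(0, n_modes, size=n)
    sd = 0.3
    y = 0.3 * x + offsets[comp] + sd * rng.normal(size=n)
    prov = {"offsets": offsets, "component_sd": sd, "base_slope": 0.3}
    return _check_finite(Dataset(x[:, None], y, np.full(n, "train"),
                                 "multimodal", ["x"], seed, provenance=prov))


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(ds: Dataset, fractions=(0.7, 0.1, 0.2),
                  seed: int = 0) -> Dataset:
    """Assign train/val/test labels (70/10/20 by default).

    Splits are a seeded permutation except for the ``series`` archetype,
    which is split contiguously in time (train earliest) because random
    splits would leak the trend.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (3,) or np.any(fractions < 0) \
            or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be 3 nonnegative reals summing to 1")
    n = ds.n
    # largest-remainder apportionment of row counts
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    for _ in range(n - counts.sum()):
        counts[np.argmax(raw - counts)] += 1
    out = ds.copy()
    labels = np.repeat(list(SPLIT_LABELS), counts)
    if ds.archetype == "series":
        order = np.arange(n) if ds.time_index is None \
            else np.argsort(ds.time_index, kind="stable")
        out.split = np.empty(n, dtype=labels.dtype)
        out.split[order] = labels
    else:
        perm = np.random.default_rng(seed).permutation(n)
        out.split = np.empty(n, dtype=labels.dtype)
        out.split[perm] = labels
    return out
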