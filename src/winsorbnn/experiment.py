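"""Orchestration of the full robustness-benchmarking protocol.

The grid is archetypes x models x noise sites x Winsorization limits x test
conditions x seeds.  Each cell: generate synthetic data (seeded), split
70/10/20, contaminate the training and validation rows with standard
Cauchy noise at the configured site (and the test rows too, under the
contaminated-test condition, from an independent stream), Winsorize the
noise-site variables of the training and validation rows at the cell's
limit, fit the model (series data are trend/seasonal-adjusted first),
predict the posterior on the test rows and record metrics.

Data for a given (archetype, repetition seed) are shared across models,
limits and conditions so that pre/post-Winsorization comparisons and
relative efficiencies are computed on identical draws.  Per-cell seeds are
derived by stable hashing, so running a subset of the grid reproduces the
corresponding cells of the full grid bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import datasets as dsmod
from .contamination import NoiseConfig, add_cauchy_noise
from .datasets import Dataset, split_dataset
from .evaluation import (MetricsReport, regression_metrics,
                         relative_efficiency, select_optimal_limit)
from .gp import GPConfig, VGPConfig, fit_exact_gp, fit_variational_gp
from .nets import (NetworkArchitecture, TrainConfig, TrainingFailure,
                   fit_baseline_mlp, fit_concrete_dropout, fit_flipout,
                   fit_mdn, predict_posterior)
from .trend import detrend, fit_trend_seasonal, retrend
from .winsorization import (DEFAULT_ALPHA_GRID, variables_for_site,
                            winsorize_dataset)

log = logging.getLogger("winsorbnn")

CONDITIONS = ("untouched", "contaminated")

#: desk-scale generation profile (full cited feature counts, modest n)
ARCHETYPE_PROFILES = {
    "crop": dict(n_sites=30, n_years=10),
    "tabular": dict(n=500, p=8, noise_sd=0.5, skew_target=False),
    "heavy_tail": dict(n=500, p=8, noise_sd=0.5, skew_target=True),
    "series": dict(n_months=480),
    "highdim": dict(n=300, p=238, k_informative=10),
}


def stable_cell_seed(global_seed: int, *key) -> int:
    """Deterministic sub-seed from (global seed, cell key), below 2^31."""
    text = f"{global_seed}|" + "|".join(str(k) for k in key)
    return zlib.crc32(text.encode()) % (2 ** 31)


@dataclass
class ExperimentConfig:
    archetypes: Tuple[str, ...] = ("crop",)
    models: Tuple[str, ...] = ("mdn:2", "concrete_dropout")
    sites: Tuple[str, ...] = ("none", "target", "features", "both")
    alphas: Tuple[float, ...] = DEFAULT_ALPHA_GRID
    conditions: Tuple[str, ...] = ("untouched",)
    seeds: Tuple[int, ...] = (0, 1, 2, 3, 4)
    preset: str = "small"
    epochs: int = 300
    lr: float = 1e-3
    patience: int = 20
    n_samples: int = 100
    m_inducing: int = 64
    out_dir: Optional[str] = None

    def __post_init__(self):
        for group in (self.archetypes, self.models, self.sites, self.alphas,
                      self.conditions, self.seeds):
            if len(group) == 0:
                raise ValueError("all grid dimensions must be nonempty")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {unknown}")

    @property
    def n_cells(self) -> int:
        return (len(self.archetypes) * len(self.models) * len(self.sites)
                * len(self.alphas) * len(self.conditions) * len(self.seeds))

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ExperimentConfig":
        d = dict(d)
        for k in ("archetypes", "models", "sites", "alphas", "conditions",
                  "seeds"):
            if k in d:
                d[k] = tuple(d[k])
        return ExperimentConfig(**d)

    @staticmethod
    def from_file(path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            return ExperimentConfig.from_dict(yaml.safe_load(text))
        return ExperimentConfig.from_dict(json.loads(text))


@dataclass
class ExperimentResult:
    records: pd.DataFrame
    config: ExperimentConfig

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        (out / "config.json").write_text(
            json.dumps(self.config.to_dict(), indent=1))

    @staticmethod
    def load(out_dir) -> "ExperimentResult":
        out = Path(out_dir)
        return ExperimentResult(
            records=pd.read_csv(out / "records.csv"),
            config=ExperimentConfig.from_dict(
                json.loads((out / "config.json").read_text())))


# ---------------------------------------------------------------------------
# model factory
# ---------------------------------------------------------------------------

def _fit_model(name: str, ds: Dataset, arch: NetworkArchitecture,
               cfg: ExperimentConfig, seed: int):
    tc = TrainConfig(lr=cfg.lr, epochs=cfg.epochs, patience=cfg.patience,
                     seed=seed, n_samples=cfg.n_samples)
    if name == "exact_gp":
        return fit_exact_gp(ds, GPConfig())
    if name == "vgp":
        m = min(cfg.m_inducing, int(ds.mask("train").sum()))
        return fit_variational_gp(ds, m_ind=m, config=VGPConfig(seed=seed))
    if name == "concrete_dropout":
        return fit_concrete_dropout(ds, arch, tc)
    if name == "baseline_mlp":
        return fit_baseline_mlp(ds, arch, tc)
    if name.startswith("flipout"):
        subset = name.split(":", 1)[1] if ":" in name else "all"
        return fit_flipout(ds, arch, flipout_layers=subset, config=tc)
    if name.startswith("mdn"):
        k = int(name.split(":", 1)[1]) if ":" in name else 2
        return fit_mdn(ds, arch, K=k, config=tc)
    raise ValueError(f"unknown model {name!r}")


def generate_archetype(archetype: str, seed: int,
                       overrides: Optional[dict] = None) -> Dataset:
    """Seeded desk-scale dataset for an archetype, already split 70/10/20."""
    if archetype not in ARCHETYPE_PROFILES:
        raise ValueError(f"unknown archetype {archetype!r}")
    kw = dict(ARCHETYPE_PROFILES[archetype])
    kw.update(overrides or {})
    maker = {"crop": dsmod.make_crop_archetype,
             "tabular": dsmod.make_tabular_regression,
             "heavy_tail": dsmod.make_tabular_regression,
             "series": dsmod.make_trend_seasonal_series,
             "highdim": dsmod.make_highdim_lowsample}[archetype]
    ds = maker(seed=seed, **kw)
    return split_dataset(ds, (0.7, 0.1, 0.2),
                         seed=stable_cell_seed(seed, "split"))


# ---------------------------------------------------------------------------
# grid runner
# ---------------------------------------------------------------------------

def _run_cell(cfg: ExperimentConfig, arch: NetworkArchitecture,
              ds_treated: Dataset, ds_eval: Dataset, model_name: str,
              fit_seed: int, condition: str, alpha: float) -> dict:
    """Fit one model on the treated data and evaluate on the test rows."""
    t0 = time.perf_counter()
    test_mask = ds_eval.mask("test")
    X_test = ds_eval.features[test_mask]
    y_test = ds_eval.target[test_mask]
    if ds_treated.archetype == "series" and ds_treated.time_index is not None:
        tr_mask = ds_treated.mask("train")
        tm = fit_trend_seasonal(ds_treated.time_index[tr_mask],
                                ds_treated.target[tr_mask])
        resid_ds = ds_treated.copy()
        adj = ds_treated.mask("train", "val")
        resid_ds.target[adj] = detrend(tm, ds_treated.time_index[adj],
                                       ds_treated.target[adj])
        model = _fit_model(model_name, resid_ds, arch, cfg, fit_seed)
        pred = predict_posterior(model, X_test, S=cfg.n_samples,
                                 seed=fit_seed)
        pred.mean = retrend(tm, ds_eval.time_index[test_mask], pred.mean)
        pred.samples = None
    else:
        model = _fit_model(model_name, ds_treated, arch, cfg, fit_seed)
        pred = predict_posterior(model, X_test, S=cfg.n_samples,
                                 seed=fit_seed)
    rep = regression_metrics(y_test, pred, condition=condition,
                             winsorized=alpha > 0)
    out = rep.to_dict()
    out["runtime_s"] = time.perf_counter() - t0
    return out


def run_grid(config: ExperimentConfig) -> ExperimentResult:
    """Run every cell of the configured grid and collect long-format records.

    A model-training failure is recorded as a flagged row (NaN metrics),
    never an abort.  With ``config.out_dir`` set, records are checkpointed
    to CSV as they complete.
    """
    arch = NetworkArchitecture.preset(config.preset)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(
            json.dumps(config.to_dict(), indent=1))
    records = []
    metric_cols = ["mse", "mae", "median_ae", "r2", "mean_pred_std",
                   "sup_abs_error", "n_test", "runtime_s"]
    for archetype in config.archetypes:
        for seed in config.seeds:
            data_seed = stable_cell_seed(seed, archetype, "data")
            ds = generate_archetype(archetype, data_seed)
            for site in config.sites:
                noise_seed = stable_cell_seed(seed, archetype, site, "noise")
                contaminated = add_cauchy_noise(
                    ds, NoiseConfig(site=site, seed=noise_seed))
                eval_sets = {}
                if "untouched" in config.conditions:
                    eval_sets["untouched"] = ds
                if "contaminated" in config.conditions:
                    test_seed = stable_cell_seed(seed, archetype, site,
                                                 "test-noise")
                    eval_sets["contaminated"] = add_cauchy_noise(
                        ds, NoiseConfig(site=site, seed=test_seed,
                                        subsets=frozenset({"test"})))
                for alpha in config.alphas:
                    treated, _ = winsorize_dataset(
                        contaminated, alpha,
                        variables=variables_for_site(site))
                    for model_name in config.models:
                        fit_seed = stable_cell_seed(seed, archetype, site,
                                                    model_name, "fit")
                        for condition in config.conditions:
                            key = dict(archetype=archetype, model=model_name,
                                       site=site, alpha=alpha,
                                       condition=condition, seed=seed)
                            try:
                                cell = _run_cell(config, arch, treated,
                                                 eval_sets[condition],
                                                 model_name, fit_seed,
                                                 condition, alpha)
                                cell["failed"] = False
                            except (TrainingFailure, FloatingPointError,
                                    np.linalg.LinAlgError) as exc:
                                log.warning("cell %s failed: %s", key, exc)
                                cell = {c: np.nan for c in metric_cols}
                                cell.update(condition=condition,
                                            winsorized=alpha > 0,
                                            failed=True)
                            records.append({**key, **cell})
                            log.info("cell %s done (%.2fs)", key,
                                     cell.get("runtime_s", float("nan")))
                            if out_dir:
                                pd.DataFrame(records).to_csv(
                                    out_dir / "records.csv", index=False)
    result = ExperimentResult(records=pd.DataFrame(records), config=config)
    if out_dir:
        result.save(out_dir)
    return result


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize(result: ExperimentResult) -> Dict[str, pd.DataFrame]:
    """Optimal-limit metric pairs, relative efficiencies and uncertainty.

    For each (archetype, site, model, condition): the optimal limit
    minimizes the seed-mean Winsorized test MSE over the configured grid;
    the pre-treatment column is the limit-zero value.  RE = MSE / MSE_W,
    computed per seed at the selected limit and averaged.
    """
    rec = result.records
    rec = rec[~rec["failed"].astype(bool)]
    if rec.empty:
        raise ValueError("no successful records to summarize")
    rows, re_rows = [], []
    group_cols = ["archetype", "site", "model", "condition"]
    for keys, g in rec.groupby(group_cols):
        per_alpha = {a: gg["mse"].tolist()
                     for a, gg in g.groupby("alpha") if len(gg)}
        if 0.0 not in per_alpha:
            continue
        opt = select_optimal_limit(per_alpha)
        base = g[g["alpha"] == 0.0].set_index("seed")
        wins = g[g["alpha"] == opt].set_index("seed")
        shared = base.index.intersection(wins.index)
        base, wins = base.loc[shared], wins.loc[shared]
        row = dict(zip(group_cols, keys))
        row.update(optimal_limit=opt,
                   mse=base["mse"].mean(), mse_w=wins["mse"].mean(),
                   r2=base["r2"].mean(), r2_w=wins["r2"].mean(),
                   median_ae=base["median_ae"].mean(),
                   median_ae_w=wins["median_ae"].mean(),
                   mae=base["mae"].mean(), mae_w=wins["mae"].mean(),
                   n_seeds=len(shared))
        rows.append(row)
        res = [relative_efficiency(b, w) for b, w in
               zip(base["mse"], wins["mse"]) if w > 0]
        sup_holds = (wins["sup_abs_error"].to_numpy()
                     <= base["sup_abs_error"].to_numpy())
        re_rows.append(dict(zip(group_cols, keys)) | dict(
            optimal_limit=opt, re_mean=float(np.mean(res)),
            re_median=float(np.median(res)),
            sup_error_improved_fraction=float(np.mean(sup_holds))))
    uncertainty = (rec.groupby(group_cols + ["alpha"])["mean_pred_std"]
                   .mean().reset_index())
    return {"optimal_limit": pd.DataFrame(rows),
            "relative_efficiency": pd.DataFrame(re_rows),
            "uncertainty": uncertainty}
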