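"""Generate the five synthetic regression archetypes.

Each generator is a pure function of its arguments and records its planted
ground truth in the provenance dictionary, so downstream recovery tests
(and your own sanity checks) need no re-derivation.
"""

import numpy as np

import winsorbnn as w

crop = w.make_crop_archetype(n_sites=30, n_years=5, seed=0)
print(f"crop:      {crop.n} site-year rows x {crop.p} features "
      "(365 tmax + 365 tmin + 365 prcp + lon/lat + trig)")
print(f"           planted harvest-precipitation coefficient: "
      f"{crop.provenance['coef']['harvest_prcp']} (wet harvests hurt yield)")

tab = w.make_tabular_regression(n=500, p=8, noise_sd=0.5, seed=0)
print(f"tabular:   {tab.n} rows x {tab.p} features, noise sd 0.5")

heavy = w.make_tabular_regression(n=500, p=8, noise_sd=0.5,
                                  skew_target=True, seed=0)
from scipy.stats import skew
print(f"heavy_tail: target skewness {skew(heavy.target):.2f} "
      "(right-skewed burned-area style)")

series = w.make_trend_seasonal_series(n_months=480, slope=0.05, seed=0)
print(f"series:    {series.n} months, planted slope "
      f"{series.provenance['slope']} per month + 12-month seasonality")

hd = w.make_highdim_lowsample(n=300, p=238, k_informative=10, seed=0)
print(f"highdim:   {hd.n} samples x {hd.p} features, signal in "
      f"{len(hd.provenance['informative'])} columns, 4 latent groups")

sp = w.split_dataset(tab, (0.7, 0.1, 0.2), seed=0)
counts = {s: int(sp.mask(s).sum()) for s in ("train", "val", "test")}
print(f"70/10/20 split of n=500: {counts}")
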