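"""Cauchy contamination and its Winsorization treatment.

Adds i.i.d. standard Cauchy noise to the training/validation targets of a
tabular dataset, then Winsorizes the target at the 5% limit.  Because the
Cauchy distribution has no finite moments, a handful of draws are enormous;
clipping to the central order statistics restores a usable training signal
while test rows stay untouched.
"""

import numpy as np

import winsorbnn as w

ds = w.split_dataset(w.make_tabular_regression(500, 8, 0.5, seed=0),
                     (0.7, 0.1, 0.2), seed=0)
noisy = w.add_cauchy_noise(ds, w.NoiseConfig(site="target", seed=1))
treated, spec = w.winsorize_dataset(noisy, alpha=0.05, variables="target")

m = ds.mask("train", "val")
print(f"clean target      : var {ds.target[m].var():12.2f}  "
      f"max |y| {np.abs(ds.target[m]).max():12.2f}")
print(f"contaminated      : var {noisy.target[m].var():12.2f}  "
      f"max |y| {np.abs(noisy.target[m]).max():12.2f}")
print(f"winsorized (5%)   : var {treated.target[m].var():12.2f}  "
      f"max |y| {np.abs(treated.target[m]).max():12.2f}")
print(f"replacement bounds: [{spec.lower['target']:.2f}, "
      f"{spec.upper['target']:.2f}]")
t = ds.mask("test")
print("test rows modified:", bool(np.any(treated.target[t] != ds.target[t])))
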