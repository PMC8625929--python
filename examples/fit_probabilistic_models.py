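"""Fit the five probabilistic regression families on one dataset.

All models share the posterior-prediction contract: a predictive mean and
an epistemic standard deviation per test point.  The exact GP and the
sparse variational GP are closed form; concrete dropout and flipout report
the spread of 100 stochastic forward passes; the mixture density network
uses the closed-form mixture moments.
"""

import numpy as np

import winsorbnn as w

ds = w.split_dataset(w.make_tabular_regression(400, 5, 0.3, seed=2),
                     (0.7, 0.1, 0.2), seed=0)
Xte, yte = ds.rows("test")
arch = w.NetworkArchitecture((32, 32))
cfg = w.TrainConfig(epochs=300, seed=0)

models = {
    "exact GP":          w.fit_exact_gp(ds),
    "variational GP":    w.fit_variational_gp(ds, m_ind=40,
                                              config=w.VGPConfig(seed=0)),
    "concrete dropout":  w.fit_concrete_dropout(ds, arch, cfg),
    "flipout (all)":     w.fit_flipout(ds, arch, "all", cfg),
    "MDN (2 comps)":     w.fit_mdn(ds, arch, K=2, config=cfg),
}

print(f"{'model':<18} {'test MSE':>9} {'R^2':>7} {'mean pred sd':>13}")
for name, model in models.items():
    pred = w.predict_posterior(model, Xte, S=100, seed=0)
    rep = w.regression_metrics(yte, pred)
    print(f"{name:<18} {rep.mse:9.3f} {rep.r2:7.3f} {rep.mean_pred_std:13.3f}")
# Mean predictive sd is the epistemic-uncertainty summary: how much the
# model's own posterior spreads its mean prediction at the test points.
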