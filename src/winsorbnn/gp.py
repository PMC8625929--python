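"""Exact and sparse variational Gaussian-process regression.

The exact GP places a Gaussian-process prior with constant mean and an RBF
covariance on the regression function, conditions on the training data in
closed form, and tunes exactly two hyperparameters — the kernel amplitude
and lengthscale — by maximizing the log marginal likelihood

    log p(y | X, theta) = -1/2 log|S| - 1/2 (y-mu)^T S^{-1} (y-mu)
                          - n/2 log(2 pi),      S = K + sigma_n^2 I.

The observation-noise variance is held fixed (default 1e-2 on the
standardized target scale) so the trainable-hyperparameter count is two;
the constant prior mean is the training-target mean.

The sparse variational GP summarizes the posterior through m inducing
variables u at locations Z with a Gaussian variational distribution
q(u) = N(m_u, S_u).  Its evidence lower bound decomposes over data points,

    L' = sum_i [ log N(y_i | k_i^T Kmm^{-1} m_u, beta^{-1})
                 - beta/2 * ktilde_ii - 1/2 tr(S_u Lambda_i) ]
         - KL[q(u) || p(u)],

with ktilde_ii = k_ii - k_i^T Kmm^{-1} k_i and
Lambda_i = beta Kmm^{-1} k_i k_i^T Kmm^{-1}; collapsing q(u) to its optimum
gives the equivalent bound log N(y | 0, Knm Kmm^{-1} Kmn + beta^{-1} I)
- beta/2 tr(Ktilde), which equals the exact log marginal likelihood when
Z = X.  Inducing locations, variational parameters, kernel hyperparameters
and the noise precision beta are optimized jointly by gradient ascent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from . import _autodiff as ad
from .datasets import Dataset
from .prediction import PosteriorPrediction


class NumericalFailure(RuntimeError):
    """Covariance factorization failed even after jitter escalation."""


class DegenerateInput(ValueError):
    """Input data are degenerate for the requested fit."""


# ---------------------------------------------------------------------------
# kernel and linear algebra helpers
# ---------------------------------------------------------------------------

def _sqdist(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    s1 = np.sum(X1 ** 2, axis=1)[:, None]
    s2 = np.sum(X2 ** 2, axis=1)[None, :]
    return np.maximum(s1 + s2 - 2.0 * X1 @ X2.T, 0.0)


def rbf_kernel(X1: np.ndarray, X2: np.ndarray, amplitude: float,
               lengthscale: float) -> np.ndarray:
    """amplitude^2 * exp(-||x - x'||^2 / (2 lengthscale^2))."""
    if amplitude <= 0 or lengthscale <= 0:
        raise ValueError("amplitude and lengthscale must be positive")
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("X1 and X2 must share column count")
    return amplitude ** 2 * np.exp(-_sqdist(X1, X2) / (2.0 * lengthscale ** 2))


def _chol_jitter(K: np.ndarray, jitter: float = 1e-6,
                 max_jitter: float = 1e-2):
    """Cholesky with escalating diagonal jitter (x10 up to max_jitter)."""
    j = jitter
    while True:
        try:
            return cho_factor(K + j * np.eye(K.shape[0]), lower=True), j
        except np.linalg.LinAlgError:
            j *= 10.0
            if j > max_jitter:
                raise NumericalFailure(
                    f"covariance not positive-definite at jitter {max_jitter}")


# ---------------------------------------------------------------------------
# exact GP
# ---------------------------------------------------------------------------

@dataclass
class GPConfig:
    noise_variance: float = 1e-2     # fixed, not trained
    jitter: float = 1e-6
    max_jitter: float = 1e-2
    maxiter: int = 100
    init_amplitude: float = 1.0
    init_lengthscale: Optional[float] = None  # None -> median heuristic
    standardize: bool = True


@dataclass
class GPModel:
    """Fitted exact GP: two trainable hyperparameters plus cached solves."""

    amplitude: float
    lengthscale: float
    noise_variance: float = 1e-2
    mean_constant: float = 0.0
    X_train: Optional[np.ndarray] = None
    y_train: Optional[np.ndarray] = None
    jitter: float = 1e-6
    max_jitter: float = 1e-2
    # standardization statistics (identity when unused)
    x_mean: Optional[np.ndarray] = None
    x_std: Optional[np.ndarray] = None
    y_mean: float = 0.0
    y_std: float = 1.0

    n_trainable_parameters: int = field(default=2, init=False)

    def to_dict(self) -> dict:
        return {"amplitude": self.amplitude, "lengthscale": self.lengthscale,
                "noise_variance": self.noise_variance,
                "mean_constant": self.mean_constant}

    def _scale_x(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.x_mean is None:
            return X
        return (X - self.x_mean) / self.x_std


def gp_log_marginal_likelihood(model: GPModel, X: np.ndarray,
                               y: np.ndarray) -> float:
    """Log marginal likelihood of (X, y) on the model's internal scale."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    K = rbf_kernel(X, X, model.amplitude, model.lengthscale) \
        + model.noise_variance * np.eye(n)
    (c, low), _ = _chol_jitter(K, model.jitter, model.max_jitter)
    resid = y - model.mean_constant
    alpha = cho_solve((c, low), resid)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return float(-0.5 * logdet - 0.5 * resid @ alpha
                 - 0.5 * n * np.log(2.0 * np.pi))


def _lml_and_grad(log_params, X, y, noise_variance, mean_constant, jitter,
                  max_jitter):
    """Negative lml and gradient w.r.t. (log amplitude, log lengthscale)."""
    amp, ls = np.exp(log_params)
    n = y.size
    D = _sqdist(X, X)
    K = amp ** 2 * np.exp(-D / (2.0 * ls ** 2))
    S = K + noise_variance * np.eye(n)
    (c, low), _ = _chol_jitter(S, jitter, max_jitter)
    resid = y - mean_constant
    alpha = cho_solve((c, low), resid)
    Sinv = cho_solve((c, low), np.eye(n))
    lml = (-np.sum(np.log(np.diag(c))) - 0.5 * resid @ alpha
           - 0.5 * n * np.log(2.0 * np.pi))
    W = np.outer(alpha, alpha) - Sinv          # d lml/dS = W/2
    dS_damp = 2.0 * K                          # d/d log amplitude
    dS_dls = K * (D / ls ** 2)                 # d/d log lengthscale
    grad = 0.5 * np.array([np.sum(W * dS_damp), np.sum(W * dS_dls)])
    return -lml, -grad


def fit_exact_gp(ds: Dataset, config: Optional[GPConfig] = None) -> GPModel:
    """Fit amplitude and lengthscale by maximizing the log marginal likelihood.

    Features and target are z-scored with training-row statistics (GPs are
    scale-sensitive); predictions are reported back on the original scale.
    Initialization: amplitude 1, lengthscale at the median pairwise
    training distance.  The returned hyperparameters never have a lower
    objective than the initialization.
    """
    config = config or GPConfig()
    X, y = ds.rows("train")
    if X.shape[0] < 2:
        raise DegenerateInput("need at least 2 training rows")
    if np.all(np.std(X, axis=0) == 0):
        raise DegenerateInput("all features constant")
    x_mean = x_std = None
    y_mean, y_std = 0.0, 1.0
    if config.standardize:
        x_mean = X.mean(axis=0)
        x_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        X = (X - x_mean) / x_std
        y_mean, y_std = float(y.mean()), float(max(y.std(), 1e-12))
        y = (y - y_mean) / y_std

    mean_constant = float(y.mean())
    if config.init_lengthscale is None:
        d = np.sqrt(_sqdist(X, X))
        off = d[np.triu_indices_from(d, k=1)]
        init_ls = float(np.median(off[off > 0])) if np.any(off > 0) else 1.0
    else:
        init_ls = config.init_lengthscale
    x0 = np.log([config.init_amplitude, init_ls])

    args = (X, y, config.noise_variance, mean_constant, config.jitter,
            config.max_jitter)
    res = minimize(_lml_and_grad, x0, args=args, jac=True, method="L-BFGS-B",
                   options={"maxiter": config.maxiter})
    best = res.x if res.fun <= _lml_and_grad(x0, *args)[0] else x0
    amp, ls = np.exp(best)
    return GPModel(amplitude=float(amp), lengthscale=float(ls),
                   noise_variance=config.noise_variance,
                   mean_constant=mean_constant, X_train=X, y_train=y,
                   jitter=config.jitter, max_jitter=config.max_jitter,
                   x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std)


def gp_posterior_predict(model: GPModel, X_star: np.ndarray
                         ) -> PosteriorPrediction:
    """Closed-form Gaussian conditioning; reported on the original scale."""
    if model.X_train is None:
        raise RuntimeError("model is not fitted")
    Xs = model._scale_x(X_star)
    K = rbf_kernel(model.X_train, model.X_train, model.amplitude,
                   model.lengthscale) \
        + model.noise_variance * np.eye(model.X_train.shape[0])
    (c, low), _ = _chol_jitter(K, model.jitter, model.max_jitter)
    Ks = rbf_kernel(model.X_train, Xs, model.amplitude, model.lengthscale)
    resid = model.y_train - model.mean_constant
    mean = model.mean_constant + Ks.T @ cho_solve((c, low), resid)
    v = cho_solve((c, low), Ks)
    var = model.amplitude ** 2 - np.sum(Ks * v, axis=0) + model.noise_variance
    var = np.maximum(var, 0.0)
    return PosteriorPrediction(mean=mean * model.y_std + model.y_mean,
                               std=np.sqrt(var) * model.y_std)


# ---------------------------------------------------------------------------
# sparse variational GP
# ---------------------------------------------------------------------------

@dataclass
class VGPConfig:
    iters: int = 300
    lr: float = 5e-2
    jitter: float = 1e-6
    max_jitter: float = 1e-2
    init_amplitude: float = 1.0
    init_lengthscale: Optional[float] = None
    init_beta: float = 10.0
    optimize_inducing: bool = True
    standardize: bool = True
    seed: int = 0
    checkpoint_every: int = 10


@dataclass
class VGPModel:
    """Sparse variational GP state: q(u) = N(q_mu, q_L q_L^T) at Z."""

    Z: np.ndarray                  # (m, p) inducing locations
    q_mu: np.ndarray               # (m,)
    q_L: np.ndarray                # (m, m) lower Cholesky of S_u
    amplitude: float
    lengthscale: float
    beta: float                    # noise precision
    jitter: float = 1e-6
    x_mean: Optional[np.ndarray] = None
    x_std: Optional[np.ndarray] = None
    y_mean: float = 0.0
    y_std: float = 1.0
    elbo_trace: list = field(default_factory=list)

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def _scale_x(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.x_mean is None:
            return X
        return (X - self.x_mean) / self.x_std

    def to_dict(self) -> dict:
        return {"amplitude": self.amplitude, "lengthscale": self.lengthscale,
                "beta": self.beta, "m_inducing": int(self.Z.shape[0])}


def svgp_elbo(model: VGPModel, X: np.ndarray, y: np.ndarray,
              return_parts: bool = False):
    """Uncollapsed per-point sparse-GP bound minus KL[q(u) || p(u)]."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    m = model.Z.shape[0]
    Kmm = rbf_kernel(model.Z, model.Z, model.amplitude, model.lengthscale)
    (c, low), _ = _chol_jitter(Kmm, model.jitter)
    Knm = rbf_kernel(X, model.Z, model.amplitude, model.lengthscale)
    A = cho_solve((c, low), Knm.T)                     # Kmm^{-1} Kmn, (m, n)
    mean = A.T @ model.q_mu
    ktilde = np.maximum(model.amplitude ** 2 - np.sum(Knm * A.T, axis=1), 0.0)
    S = model.q_L @ model.q_L.T
    tr_SLambda = model.beta * np.sum((model.q_L.T @ A) ** 2, axis=0)
    beta = model.beta
    fit = (-0.5 * n * np.log(2.0 * np.pi) + 0.5 * n * np.log(beta)
           - 0.5 * beta * np.sum((y - mean) ** 2))
    trace_term = -0.5 * beta * np.sum(ktilde)
    s_term = -0.5 * np.sum(tr_SLambda)
    # KL[N(q_mu, S) || N(0, Kmm)]
    Kinv_S = cho_solve((c, low), S)
    logdet_K = 2.0 * np.sum(np.log(np.diag(c)))
    logdet_S = 2.0 * np.sum(np.log(np.abs(np.diag(model.q_L))))
    kl = 0.5 * (np.trace(Kinv_S) + model.q_mu @ cho_solve((c, low), model.q_mu)
                - m + logdet_K - logdet_S)
    elbo = float(fit + trace_term + s_term - kl)
    if return_parts:
        return {"elbo": elbo, "fit": float(fit), "trace": float(trace_term),
                "s_term": float(s_term), "kl": float(kl)}
    return elbo


def svgp_collapsed_bound(model: VGPModel, X: np.ndarray,
                         y: np.ndarray) -> float:
    """Collapsed bound log N(y | 0, Qnn + beta^{-1} I) - beta/2 tr(Ktilde).

    With Z = X the trace term vanishes and the bound equals the exact GP log
    marginal likelihood at noise variance 1/beta (zero prior mean).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    Kmm = rbf_kernel(model.Z, model.Z, model.amplitude, model.lengthscale)
    (c, low), _ = _chol_jitter(Kmm, model.jitter)
    Knm = rbf_kernel(X, model.Z, model.amplitude, model.lengthscale)
    Qnn = Knm @ cho_solve((c, low), Knm.T)
    ktilde = np.maximum(model.amplitude ** 2 - np.diag(Qnn), 0.0)
    S = Qnn + (1.0 / model.beta) * np.eye(n)
    (cs, lows), _ = _chol_jitter(S, model.jitter)
    alpha = cho_solve((cs, lows), y)
    lml = (-np.sum(np.log(np.diag(cs))) - 0.5 * y @ alpha
           - 0.5 * n * np.log(2.0 * np.pi))
    return float(lml - 0.5 * model.beta * np.sum(ktilde))


def _collapsed_bound_graph(params, X, y, jitter):
    """Collapsed sparse-GP bound as an autodiff graph (scalar Tensor).

    This is the per-point bound maximized analytically over q(u): gradient
    ascent on it plus the closed-form optimum of q(u) is joint optimization
    of inducing locations, kernel hyperparameters, noise precision and the
    variational distribution (variational EM).
    """
    T = ad.Tensor
    n, m = X.shape[0], params["Z"].shape[0]
    Z = params["Z"]
    amp2 = (params["log_amp"] * 2.0).exp()
    ls2 = (params["log_ls"] * 2.0).exp()
    beta = params["log_beta"].exp()

    def k_cross(A_t, B_t):
        sa = (A_t ** 2).sum(axis=1, keepdims=True)
        sb = (B_t ** 2).sum(axis=1, keepdims=True)
        d2 = sa + sb.T - (A_t @ B_t.T) * 2.0
        return amp2 * ((d2 * -1.0) / (ls2 * 2.0)).exp()

    Xt = T(X)
    Kmm = k_cross(Z, Z) + T(np.eye(m) * jitter)
    Knm = k_cross(Xt, Z)
    Qnn = Knm @ ad.solve_psd(Kmm, Knm.T)
    ktilde = amp2 * float(n) - (Qnn * np.eye(n)).sum()
    B = Qnn + (1.0 / beta) * T(np.eye(n))
    alpha = ad.solve_psd(B, T(y))
    lml = (ad.logdet_psd(B) * -0.5 - (T(y) * alpha).sum() * 0.5
           - 0.5 * n * np.log(2.0 * np.pi))
    return lml - ktilde * beta * 0.5


def _optimal_q(Z, X, y, amplitude, lengthscale, beta, jitter):
    """Closed-form optimal q(u) = N(m*, S*) for fixed hyperparameters."""
    m = Z.shape[0]
    Kmm = rbf_kernel(Z, Z, amplitude, lengthscale) + jitter * np.eye(m)
    Knm = rbf_kernel(X, Z, amplitude, lengthscale)
    A = Kmm + beta * Knm.T @ Knm
    (ca, lowa), _ = _chol_jitter(A, jitter)
    S = Kmm @ cho_solve((ca, lowa), Kmm)
    S = 0.5 * (S + S.T)
    q_mu = beta * Kmm @ cho_solve((ca, lowa), Knm.T @ y)
    # Cholesky of S with escalation for numerical safety
    (cs, _), _ = _chol_jitter(S, max(jitter, 1e-12))
    return q_mu, np.tril(cs)


def fit_variational_gp(ds: Dataset, m_ind: int = 64,
                       config: Optional[VGPConfig] = None) -> VGPModel:
    """Jointly optimize Z, q(u), kernel hyperparameters and beta by Adam.

    Inducing locations are initialized by seeded subsampling of the
    training rows.  The best checkpointed parameter set (by bound value)
    is returned, so the final bound is never below its initial value.
    """
    config = config or VGPConfig()
    if m_ind < 1:
        raise ValueError("m_ind must be >= 1")
    X, y = ds.rows("train")
    if m_ind > X.shape[0]:
        raise ValueError("m_ind must not exceed the training-row count")
    x_mean = x_std = None
    y_mean, y_std = 0.0, 1.0
    if config.standardize:
        x_mean = X.mean(axis=0)
        x_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        X = (X - x_mean) / x_std
        y_mean, y_std = float(y.mean()), float(max(y.std(), 1e-12))
        y = (y - y_mean) / y_std

    rng = np.random.default_rng(config.seed)
    idx = rng.choice(X.shape[0], size=m_ind, replace=False)
    if config.init_lengthscale is None:
        d = np.sqrt(_sqdist(X, X))
        off = d[np.triu_indices_from(d, k=1)]
        init_ls = float(np.median(off[off > 0])) if np.any(off > 0) else 1.0
    else:
        init_ls = config.init_lengthscale

    T = ad.Tensor
    params = {
        "Z": T(X[idx].copy(), requires_grad=config.optimize_inducing),
        "log_amp": T(np.log(config.init_amplitude), requires_grad=True),
        "log_ls": T(np.log(init_ls), requires_grad=True),
        "log_beta": T(np.log(config.init_beta), requires_grad=True),
    }
    opt_params = [p for p in params.values() if p.requires_grad]
    opt = ad.Adam(opt_params, lr=config.lr)

    def snapshot():
        Z = params["Z"].data.copy()
        amp = float(np.exp(params["log_amp"].data))
        ls = float(np.exp(params["log_ls"].data))
        beta = float(np.exp(params["log_beta"].data))
        q_mu, q_L = _optimal_q(Z, X, y, amp, ls, beta, config.jitter)
        return VGPModel(Z=Z, q_mu=q_mu, q_L=q_L, amplitude=amp,
                        lengthscale=ls, beta=beta, jitter=config.jitter,
                        x_mean=x_mean, x_std=x_std, y_mean=y_mean,
                        y_std=y_std)

    best_model = snapshot()
    best_elbo = svgp_collapsed_bound(best_model, X, y)
    trace = [best_elbo]
    for it in range(config.iters):
        opt.zero_grad()
        loss = -_collapsed_bound_graph(params, X, y, config.jitter)
        loss.backward()
        opt.step()
        if (it + 1) % config.checkpoint_every == 0 or it == config.iters - 1:
            cand = snapshot()
            val = svgp_collapsed_bound(cand, X, y)
            trace.append(val)
            if val > best_elbo:
                best_elbo, best_model = val, cand
    best_model.elbo_trace = trace
    return best_model


def vgp_posterior_predict(model: VGPModel, X_star: np.ndarray
                          ) -> PosteriorPrediction:
    """Sparse posterior predictive; reported on the original scale."""
    Xs = model._scale_x(X_star)
    Kmm = rbf_kernel(model.Z, model.Z, model.amplitude, model.lengthscale)
    (c, low), _ = _chol_jitter(Kmm, model.jitter)
    Ksm = rbf_kernel(Xs, model.Z, model.amplitude, model.lengthscale)
    A = cho_solve((c, low), Ksm.T)                 # (m, n*)
    mean = A.T @ model.q_mu
    S = model.q_L @ model.q_L.T
    var = (model.amplitude ** 2 - np.sum(Ksm * A.T, axis=1)
           + np.sum(A * (S @ A), axis=0) + 1.0 / model.beta)
    var = np.maximum(var, 0.0)
    return PosteriorPrediction(mean=mean * model.y_std + model.y_mean,
                               std=np.sqrt(var) * model.y_std)
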