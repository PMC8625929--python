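"""Probabilistic neural regressors: concrete dropout, flipout, and MDN.

All three share a fully connected rectifier backbone and a common posterior
prediction contract (:class:`~winsorbnn.prediction.PosteriorPrediction`).

* Concrete dropout learns a per-layer dropout probability by replacing the
  Bernoulli mask with its concrete (sigmoid-relaxed) surrogate
  z = sigmoid((log p - log(1-p) + log u - log(1-u)) / t), which admits
  pathwise gradients; the variational regularizer combines a weight-decay
  term l^2 (1-p) ||W||^2 / (2N) with an entropy reward K H(p) / N, where
  H(p) is the Bernoulli entropy and K the number of weights feeding the
  layer.  Dropout stays active at test time, so repeated forward passes
  draw from the predictive distribution.

* The flipout network places a mean-field Gaussian posterior
  N(mu, softplus(rho)^2) on the weights of designated layers and minimizes
  the variational free energy KL[q(W)||p(W)] - E_q[log p(D|W)].  Within a
  minibatch the shared Gaussian weight perturbation is decorrelated across
  examples by elementwise +-1 sign vectors: Delta W_n = Delta W_hat o r_n
  s_n^T, which lowers the variance of stochastic gradient estimates without
  biasing them.

* The mixture density network emits mixture weights (softmax), component
  means and component scales (softplus) of a conditional Gaussian mixture
  and minimizes the negative log likelihood, evaluated in log space.

Training is full-batch Adam with early stopping on the validation loss.
Inputs are z-scored and targets centred/scaled by post-treatment training
statistics; predictions are reported on the original target scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .datasets import Dataset
from .prediction import PosteriorPrediction

#: the benchmark's 14-hidden-layer fully connected architecture
FULL_WIDTHS = (52, 250, 300, 450, 202, 452, 50, 300, 200, 52, 400, 350,
               450, 450)
#: desk-scale preset used by the default experiment profile and the tests
SMALL_WIDTHS = (32, 32)


class TrainingFailure(RuntimeError):
    """Loss became non-finite during training."""


@dataclass(frozen=True)
class NetworkArchitecture:
    hidden_widths: Tuple[int, ...] = SMALL_WIDTHS
    activation: str = "relu"

    def __post_init__(self):
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("all layer widths must be >= 1")

    @staticmethod
    def preset(name: str) -> "NetworkArchitecture":
        if name == "full":
            return NetworkArchitecture(FULL_WIDTHS)
        if name == "small":
            return NetworkArchitecture(SMALL_WIDTHS)
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 300
    patience: int = 20           # early stopping on validation loss
    seed: int = 0
    n_samples: int = 100         # test-time stochastic forward passes
    grad_clip: float = 100.0


# ---------------------------------------------------------------------------
# shared pieces
# ---------------------------------------------------------------------------

def _init_layers(rng, widths: Sequence[int]) -> List[Tuple[np.ndarray,
                                                           np.ndarray]]:
    """He-style initial (W, b) pairs for consecutive width pairs."""
    out = []
    for d_in, d_out in zip(widths[:-1], widths[1:]):
        W = rng.normal(scale=np.sqrt(2.0 / d_in), size=(d_in, d_out))
        out.append((W, np.zeros(d_out)))
    return out


@dataclass
class _Scaler:
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float

    @staticmethod
    def fit(X: np.ndarray, y: np.ndarray) -> "_Scaler":
        sd = X.std(axis=0)
        return _Scaler(X.mean(axis=0), np.where(sd > 0, sd, 1.0),
                       float(y.mean()), float(max(y.std(), 1e-12)))

    def x(self, X):
        return (np.atleast_2d(np.asarray(X, dtype=float)) - self.x_mean) \
            / self.x_std

    def y(self, y):
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_std


def _gaussian_nll(resid_sq: Tensor, log_var: Tensor) -> Tensor:
    """Elementwise 0.5*(log 2 pi + log_var + resid^2 / var)."""
    return (log_var + resid_sq * (log_var * -1.0).exp()
            + np.log(2.0 * np.pi)) * 0.5


def _clip_grads(params, limit: float):
    for p in params:
        if p.grad is not None:
            p.grad = np.clip(np.asarray(p.grad, dtype=float), -limit, limit)


# ---------------------------------------------------------------------------
# concrete dropout
# ---------------------------------------------------------------------------

def bernoulli_entropy(p) -> np.ndarray:
    """H(p) = -p log p - (1-p) log(1-p), nats; 0 at the endpoints."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0) \
            - np.where(p < 1, (1 - p) * np.log1p(-p), 0.0)
    out = np.where((p == 0) | (p == 1), 0.0, h)
    return out if out.ndim else float(out)


def concrete_dropout_mask(p, t: float, u) -> np.ndarray:
    """Concrete (relaxed Bernoulli) keep/drop value in (0, 1).

    Monotone increasing in both u and p; at temperature t -> infinity the
    relaxation flattens to 1/2.
    """
    if np.any(np.asarray(t) <= 0):
        raise ValueError("temperature must be positive")
    p = np.asarray(p, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1) or np.any(u <= 0) or np.any(u >= 1):
        raise ValueError("p and u must lie in (0, 1)")
    logit = (np.log(p) - np.log1p(-p) + np.log(u) - np.log1p(-u)) / t
    out = 1.0 / (1.0 + np.exp(-logit))
    return out if out.ndim else float(out)


@dataclass
class ConcreteDropoutNet:
    """Concrete-dropout regressor with a heteroscedastic Gaussian head."""

    architecture: NetworkArchitecture
    n_features: int
    temperature: float = 0.1     # concrete relaxation temperature
    prior_lengthscale: float = 1e-2
    weights: List[Tensor] = field(default_factory=list)
    biases: List[Tensor] = field(default_factory=list)
    p_logits: List[Tensor] = field(default_factory=list)  # one per layer
    scaler: Optional[_Scaler] = None
    fitted: bool = False

    def __post_init__(self):
        if not self.weights:
            rng = np.random.default_rng(0)
            widths = (self.n_features, *self.architecture.hidden_widths, 2)
            for W, b in _init_layers(rng, widths):
                self.weights.append(Tensor(W, requires_grad=True))
                self.biases.append(Tensor(b, requires_grad=True))
            init_logit = np.log(0.1) - np.log(0.9)   # p starts at 0.1
            self.p_logits = [Tensor(init_logit, requires_grad=True)
                             for _ in self.weights]

    @property
    def dropout_probabilities(self) -> np.ndarray:
        return np.array([1 / (1 + np.exp(-pl.data)) for pl in self.p_logits])

    def parameters(self) -> List[Tensor]:
        return [*self.weights, *self.biases, *self.p_logits]

    def _forward(self, X: np.ndarray, rng) -> Tuple[Tensor, Tensor]:
        """One stochastic pass; returns (mean, log_var) Tensors."""
        h: Tensor = Tensor(X)
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            p = self.p_logits[i].sigmoid()
            u = rng.uniform(1e-7, 1 - 1e-7, size=h.shape)
            # relaxed drop indicator; keep prob is 1-p, inverted scaling
            logit_u = np.log(u) - np.log1p(-u)
            drop = ((p.log() - (1.0 - p).log() + logit_u)
                    * (1.0 / self.temperature)).sigmoid()
            h = h * (1.0 - drop) / (1.0 - p)
            h = h @ W + b
            if i < n_layers - 1:
                h = h.relu()
        return h[:, 0], h[:, 1]

    def predict(self, X_star: np.ndarray, S: int = 100,
                seed: int = 0) -> PosteriorPrediction:
        return predict_posterior(self, X_star, S=S, seed=seed)


def concrete_dropout_regularizer(net: ConcreteDropoutNet, N: int) -> Tensor:
    """Variational regularizer summed over layers.

    Per layer: l^2 (1-p) ||W||^2 / (2N) + ||b||^2 / (2N) - K H(p) / N with
    K the number of weights in the layer (the dimension of its weight
    vector); the precision tau is absorbed into the heteroscedastic
    likelihood head.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    l2 = net.prior_lengthscale ** 2
    total: Tensor = Tensor(0.0)
    for W, b, pl in zip(net.weights, net.biases, net.p_logits):
        p = pl.sigmoid()
        one_m_p = 1.0 - p
        entropy = -(p * p.log() + one_m_p * one_m_p.log())
        k = float(W.data.size)
        total = total + (W ** 2).sum() * one_m_p * (l2 / (2.0 * N)) \
            + (b ** 2).sum() * (1.0 / (2.0 * N)) \
            - entropy * (k / N)
    return total


def fit_concrete_dropout(ds: Dataset, arch: NetworkArchitecture = None,
                         config: TrainConfig = None) -> ConcreteDropoutNet:
    """Minimize heteroscedastic Gaussian NLL plus the dropout regularizer."""
    arch = arch or NetworkArchitecture()
    config = config or TrainConfig()
    Xtr, ytr = ds.rows("train")
    Xva, yva = ds.rows("val")
    if Xtr.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    scaler = _Scaler.fit(Xtr, ytr)
    Xs, ys = scaler.x(Xtr), scaler.y(ytr)
    has_val = Xva.shape[0] > 0
    Xv = scaler.x(Xva) if has_val else None
    yv = scaler.y(yva) if has_val else None
    N = Xs.shape[0]

    rng = np.random.default_rng(config.seed)
    net = ConcreteDropoutNet(architecture=arch, n_features=Xs.shape[1])
    # re-seed parameter init deterministically from config.seed
    init_rng = np.random.default_rng([config.seed, 1])
    widths = (Xs.shape[1], *arch.hidden_widths, 2)
    for (W, b), wt, bt in zip(_init_layers(init_rng, widths),
                              net.weights, net.biases):
        wt.data, bt.data = W, b
    net.scaler = scaler

    params = net.parameters()
    opt = ad.Adam(params, lr=config.lr)
    best = None
    best_val, wait = np.inf, 0
    for epoch in range(config.epochs):
        opt.zero_grad()
        mean, log_var = net._forward(Xs, rng)
        resid_sq = (Tensor(ys) - mean) ** 2
        loss = _gaussian_nll(resid_sq, log_var).mean() \
            + concrete_dropout_regularizer(net, N)
        if not np.isfinite(loss.data):
            raise TrainingFailure(f"non-finite loss at epoch {epoch}")
        loss.backward()
        _clip_grads(params, config.grad_clip)
        opt.step()
        if has_val:
            vrng = np.random.default_rng([config.seed, 2, epoch])
            vm, vlv = net._forward(Xv, vrng)
            vloss = float(_gaussian_nll((Tensor(yv) - vm) ** 2, vlv)
                          .mean().data)
            if vloss < best_val - 1e-9:
                best_val, wait = vloss, 0
                best = [p.data.copy() for p in params]
            else:
                wait += 1
                if wait >= config.patience:
                    break
    if best is not None:
        for p, d in zip(params, best):
            p.data = d
    net.fitted = True
    return net


# ---------------------------------------------------------------------------
# flipout
# ---------------------------------------------------------------------------

FLIPOUT_SUBSETS = ("all", "early5", "mid5", "final5")


def flipout_layer_indices(n_layers: int, tag: str) -> List[int]:
    """Which layers carry a variational posterior for a subset tag."""
    if tag not in FLIPOUT_SUBSETS:
        raise ValueError(f"unknown flipout subset {tag!r}")
    if tag == "all":
        return list(range(n_layers))
    k = min(5, n_layers)
    if tag == "early5":
        return list(range(k))
    if tag == "final5":
        return list(range(n_layers - k, n_layers))
    start = max(0, (n_layers - k) // 2)
    return list(range(start, start + k))


def gaussian_reparameterize(mu, rho, eps):
    """mu + softplus(rho) * eps; the scale is strictly positive."""
    return np.asarray(mu) + np.logaddexp(0.0, np.asarray(rho)) \
        * np.asarray(eps)


def flipout_perturb(dW_hat: np.ndarray, r: np.ndarray,
                    s: np.ndarray) -> np.ndarray:
    """Delta W_n = Delta W_hat o (r s^T) for +-1 sign vectors r, s.

    r spans the layer outputs, s the layer inputs; elementwise magnitudes
    are preserved and the expectation over signs is zero.
    """
    dW_hat = np.asarray(dW_hat, dtype=float)
    r = np.asarray(r, dtype=float).ravel()
    s = np.asarray(s, dtype=float).ravel()
    if dW_hat.shape != (r.size, s.size):
        raise ValueError("shape mismatch: dW_hat must be (len(r), len(s))")
    return dW_hat * np.outer(r, s)


@dataclass
class FlipoutNet:
    """Mean-field Gaussian BNN trained with flipout gradient decorrelation."""

    architecture: NetworkArchitecture
    n_features: int
    flipout_layers: str = "all"
    n_samples: int = 100
    # per-layer parameter tensors; variational layers get (mu, rho) pairs
    W_mu: List[Tensor] = field(default_factory=list)
    W_rho: List[Optional[Tensor]] = field(default_factory=list)
    b_mu: List[Tensor] = field(default_factory=list)
    b_rho: List[Optional[Tensor]] = field(default_factory=list)
    log_noise: Optional[Tensor] = None    # homoscedastic observation noise
    scaler: Optional[_Scaler] = None
    fitted: bool = False

    def __post_init__(self):
        if not self.W_mu:
            rng = np.random.default_rng(0)
            widths = (self.n_features, *self.architecture.hidden_widths, 1)
            var_ix = set(flipout_layer_indices(len(widths) - 1,
                                               self.flipout_layers))
            for i, (W, b) in enumerate(_init_layers(rng, widths)):
                self.W_mu.append(Tensor(W, requires_grad=True))
                self.b_mu.append(Tensor(b, requires_grad=True))
                if i in var_ix:
                    self.W_rho.append(Tensor(np.full(W.shape, -5.0),
                                             requires_grad=True))
                    self.b_rho.append(Tensor(np.full(b.shape, -5.0),
                                             requires_grad=True))
                else:
                    self.W_rho.append(None)
                    self.b_rho.append(None)
            self.log_noise = Tensor(np.log(0.5), requires_grad=True)

    @property
    def n_variational_layers(self) -> int:
        return sum(1 for r in self.W_rho if r is not None)

    def parameters(self) -> List[Tensor]:
        out = [*self.W_mu, *self.b_mu, self.log_noise]
        out += [r for r in self.W_rho if r is not None]
        out += [r for r in self.b_rho if r is not None]
        return out

    def _forward(self, X: np.ndarray, rng, use_flipout: bool = True) -> Tensor:
        """One stochastic pass; per-example flipout sign decorrelation."""
        h: Tensor = Tensor(X)
        B = X.shape[0]
        n_layers = len(self.W_mu)
        for i in range(n_layers):
            Wm, bm = self.W_mu[i], self.b_mu[i]
            if self.W_rho[i] is None:
                h = h @ Wm + bm
            else:
                sigW = self.W_rho[i].softplus()
                sigb = self.b_rho[i].softplus()
                epsW = rng.normal(size=Wm.shape)
                epsb = rng.normal(size=bm.shape)
                dW = sigW * epsW          # shared base perturbation
                db = sigb * epsb
                if use_flipout:
                    s = rng.choice([-1.0, 1.0], size=(B, h.shape[1]))
                    r = rng.choice([-1.0, 1.0], size=(B, Wm.shape[1]))
                    h = (h @ Wm) + ((h * s) @ dW) * r + bm + db
                else:
                    h = h @ (Wm + dW) + (bm + db)
            if i < n_layers - 1:
                h = h.relu()
        return h[:, 0]

    def predict(self, X_star: np.ndarray, S: int = 100,
                seed: int = 0) -> PosteriorPrediction:
        return predict_posterior(self, X_star, S=S, seed=seed)


def _flipout_kl(net: FlipoutNet) -> Tensor:
    """Closed-form KL of the mean-field posterior to the N(0,1) prior."""
    total: Tensor = Tensor(0.0)
    for mu, rho in zip((*net.W_mu, *net.b_mu), (*net.W_rho, *net.b_rho)):
        if rho is None:
            continue
        sig = rho.softplus()
        var = sig ** 2
        total = total + ((var + mu ** 2 - 1.0 - var.log()) * 0.5).sum()
    return total


def variational_free_energy(net: FlipoutNet, batch, N: int,
                            rng=None, use_flipout: bool = True) -> Tensor:
    """KL (scaled by batch/N) plus Monte-Carlo Gaussian NLL on the batch."""
    X, y = batch
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("batch must be nonempty")
    if N < y.size:
        raise ValueError("N must be at least the batch size")
    rng = rng or np.random.default_rng(0)
    mean = net._forward(X, rng, use_flipout=use_flipout)
    log_var = net.log_noise * 2.0
    nll = _gaussian_nll((Tensor(y) - mean) ** 2, log_var).sum()
    return _flipout_kl(net) * (y.size / N) + nll


def fit_flipout(ds: Dataset, arch: NetworkArchitecture = None,
                flipout_layers: str = "all",
                config: TrainConfig = None) -> FlipoutNet:
    """Minimize the variational free energy with flipout perturbations."""
    arch = arch or NetworkArchitecture()
    config = config or TrainConfig()
    Xtr, ytr = ds.rows("train")
    Xva, yva = ds.rows("val")
    scaler = _Scaler.fit(Xtr, ytr)
    Xs, ys = scaler.x(Xtr), scaler.y(ytr)
    has_val = Xva.shape[0] > 0
    Xv = scaler.x(Xva) if has_val else None
    yv = scaler.y(yva) if has_val else None
    N = Xs.shape[0]

    net = FlipoutNet(architecture=arch, n_features=Xs.shape[1],
                     flipout_layers=flipout_layers,
                     n_samples=config.n_samples)
    init_rng = np.random.default_rng([config.seed, 1])
    widths = (Xs.shape[1], *arch.hidden_widths, 1)
    for (W, b), wt, bt in zip(_init_layers(init_rng, widths),
                              net.W_mu, net.b_mu):
        wt.data, bt.data = W, b
    net.scaler = scaler

    rng = np.random.default_rng(config.seed)
    params = net.parameters()
    opt = ad.Adam(params, lr=config.lr)
    best, best_val, wait = None, np.inf, 0
    for epoch in range(config.epochs):
        opt.zero_grad()
        loss = variational_free_energy(net, (Xs, ys), N, rng=rng) \
            * (1.0 / N)
        if not np.isfinite(loss.data):
            raise TrainingFailure(f"non-finite loss at epoch {epoch}")
        loss.backward()
        _clip_grads(params, config.grad_clip)
        opt.step()
        if has_val:
            vrng = np.random.default_rng([config.seed, 2, epoch])
            vm = net._forward(Xv, vrng)
            vloss = float(((yv - vm.data) ** 2).mean())
            if vloss < best_val - 1e-9:
                best_val, wait = vloss, 0
                best = [p.data.copy() for p in params]
            else:
                wait += 1
                if wait >= config.patience:
                    break
    if best is not None:
        for p, d in zip(params, best):
            p.data = d
    net.fitted = True
    return net


# ---------------------------------------------------------------------------
# mixture density network
# ---------------------------------------------------------------------------

def mdn_negative_log_likelihood(pi, mu, sigma, y) -> float:
    """-log sum_k pi_k N(y | mu_k, sigma_k^2), via log-sum-exp."""
    pi = np.asarray(pi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if not np.isclose(pi.sum(), 1.0, atol=1e-6):
        raise ValueError("pi must sum to 1")
    log_comp = (np.log(pi) - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
                - 0.5 * ((y - mu) / sigma) ** 2)
    m = np.max(log_comp)
    return float(-(m + np.log(np.sum(np.exp(log_comp - m)))))


def mdn_predictive_moments(pi, mu, sigma) -> Tuple[float, float]:
    """Mixture mean and standard deviation (law of total variance)."""
    pi = np.asarray(pi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    mean = float(np.sum(pi * mu))
    var = float(np.sum(pi * (sigma ** 2 + mu ** 2)) - mean ** 2)
    return mean, float(np.sqrt(max(var, 0.0)))


@dataclass
class MDNModel:
    """Gaussian mixture density network with K components."""

    architecture: NetworkArchitecture
    n_features: int
    K: int = 2
    weights: List[Tensor] = field(default_factory=list)
    biases: List[Tensor] = field(default_factory=list)
    sigma_floor: float = 1e-3
    scaler: Optional[_Scaler] = None
    fitted: bool = False

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not self.weights:
            rng = np.random.default_rng(0)
            widths = (self.n_features, *self.architecture.hidden_widths,
                      3 * self.K)
            for W, b in _init_layers(rng, widths):
                self.weights.append(Tensor(W, requires_grad=True))
                self.biases.append(Tensor(b, requires_grad=True))
            # spread initial component means so components can separate
            self.biases[-1].data[self.K:2 * self.K] = \
                np.linspace(-1.0, 1.0, self.K)

    def parameters(self) -> List[Tensor]:
        return [*self.weights, *self.biases]

    def _heads(self, X: np.ndarray) -> Tuple[Tensor, Tensor, Tensor]:
        """Forward pass returning (log_pi, mu, sigma) Tensors, (n, K) each."""
        h: Tensor = Tensor(np.atleast_2d(np.asarray(X, dtype=float)))
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < n_layers - 1:
                h = h.relu()
        K = self.K
        logits = h[:, 0:K]
        log_pi = logits - ad.logsumexp(logits, axis=1, keepdims=True)
        mu = h[:, K:2 * K]
        sigma = h[:, 2 * K:3 * K].softplus() + self.sigma_floor
        return log_pi, mu, sigma

    def mixture_parameters(self, X: np.ndarray):
        """(pi, mu, sigma) arrays on the standardized target scale."""
        log_pi, mu, sigma = self._heads(self.scaler.x(X) if self.scaler
                                        else X)
        return np.exp(log_pi.data), mu.data, sigma.data

    def predict(self, X_star: np.ndarray, **kw) -> PosteriorPrediction:
        return predict_posterior(self, X_star)


def _mdn_loss(model: MDNModel, X: np.ndarray, y: np.ndarray) -> Tensor:
    log_pi, mu, sigma = model._heads(X)
    y_col = y[:, None]
    log_comp = (log_pi - sigma.log() - 0.5 * np.log(2.0 * np.pi)
                - ((Tensor(y_col) - mu) / sigma) ** 2 * 0.5)
    return -ad.logsumexp(log_comp, axis=1).mean()


def fit_mdn(ds: Dataset, arch: NetworkArchitecture = None, K: int = 2,
            config: TrainConfig = None) -> MDNModel:
    """Minimize the mixture negative log likelihood over training rows."""
    arch = arch or NetworkArchitecture()
    config = config or TrainConfig()
    Xtr, ytr = ds.rows("train")
    Xva, yva = ds.rows("val")
    scaler = _Scaler.fit(Xtr, ytr)
    Xs, ys = scaler.x(Xtr), scaler.y(ytr)
    has_val = Xva.shape[0] > 0
    Xv = scaler.x(Xva) if has_val else None
    yv = scaler.y(yva) if has_val else None

    model = MDNModel(architecture=arch, n_features=Xs.shape[1], K=K)
    init_rng = np.random.default_rng([config.seed, 1])
    widths = (Xs.shape[1], *arch.hidden_widths, 3 * K)
    for (W, b), wt, bt in zip(_init_layers(init_rng, widths),
                              model.weights, model.biases):
        wt.data, bt.data = W, b
    model.biases[-1].data[K:2 * K] = np.linspace(-1.0, 1.0, K)
    model.scaler = scaler

    params = model.parameters()
    opt = ad.Adam(params, lr=config.lr)
    best, best_val, wait = None, np.inf, 0
    for epoch in range(config.epochs):
        opt.zero_grad()
        loss = _mdn_loss(model, Xs, ys)
        if not np.isfinite(loss.data):
            raise TrainingFailure(f"non-finite loss at epoch {epoch}")
        loss.backward()
        _clip_grads(params, config.grad_clip)
        opt.step()
        if has_val:
            vloss = float(_mdn_loss(model, Xv, yv).data)
            if vloss < best_val - 1e-9:
                best_val, wait = vloss, 0
                best = [p.data.copy() for p in params]
            else:
                wait += 1
                if wait >= config.patience:
                    break
    if best is not None:
        for p, d in zip(params, best):
            p.data = d
    model.fitted = True
    return model


def mdn_held_out_nll(model: MDNModel, X: np.ndarray, y: np.ndarray) -> float:
    """Mean per-point negative log likelihood on held-out data."""
    Xs = model.scaler.x(X) if model.scaler else np.atleast_2d(X)
    ys = model.scaler.y(y) if model.scaler else np.asarray(y, dtype=float)
    return float(_mdn_loss(model, Xs, ys).data)


# ---------------------------------------------------------------------------
# deterministic baseline
# ---------------------------------------------------------------------------

@dataclass
class BaselineMLP:
    """Plain deterministic MLP trained on mean squared error.

    Serves as the non-probabilistic reference; its predictive standard
    deviation is reported as zero.
    """

    architecture: NetworkArchitecture
    n_features: int
    weights: List[Tensor] = field(default_factory=list)
    biases: List[Tensor] = field(default_factory=list)
    scaler: Optional[_Scaler] = None
    fitted: bool = False

    def __post_init__(self):
        if not self.weights:
            rng = np.random.default_rng(0)
            widths = (self.n_features, *self.architecture.hidden_widths, 1)
            for W, b in _init_layers(rng, widths):
                self.weights.append(Tensor(W, requires_grad=True))
                self.biases.append(Tensor(b, requires_grad=True))

    def parameters(self) -> List[Tensor]:
        return [*self.weights, *self.biases]

    def _forward(self, X: np.ndarray) -> Tensor:
        h: Tensor = Tensor(np.atleast_2d(np.asarray(X, dtype=float)))
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < n_layers - 1:
                h = h.relu()
        return h[:, 0]


def fit_baseline_mlp(ds: Dataset, arch: NetworkArchitecture = None,
                     config: TrainConfig = None) -> BaselineMLP:
    arch = arch or NetworkArchitecture()
    config = config or TrainConfig()
    Xtr, ytr = ds.rows("train")
    Xva, yva = ds.rows("val")
    scaler = _Scaler.fit(Xtr, ytr)
    Xs, ys = scaler.x(Xtr), scaler.y(ytr)
    has_val = Xva.shape[0] > 0
    Xv = scaler.x(Xva) if has_val else None
    yv = scaler.y(yva) if has_val else None
    model = BaselineMLP(architecture=arch, n_features=Xs.shape[1])
    init_rng = np.random.default_rng([config.seed, 1])
    widths = (Xs.shape[1], *arch.hidden_widths, 1)
    for (W, b), wt, bt in zip(_init_layers(init_rng, widths),
                              model.weights, model.biases):
        wt.data, bt.data = W, b
    model.scaler = scaler
    params = model.parameters()
    opt = ad.Adam(params, lr=config.lr)
    best, best_val, wait = None, np.inf, 0
    for epoch in range(config.epochs):
        opt.zero_grad()
        loss = ((Tensor(ys) - model._forward(Xs)) ** 2).mean()
        if not np.isfinite(loss.data):
            raise TrainingFailure(f"non-finite loss at epoch {epoch}")
        loss.backward()
        _clip_grads(params, config.grad_clip)
        opt.step()
        if has_val:
            vloss = float(((yv - model._forward(Xv).data) ** 2).mean())
            if vloss < best_val - 1e-9:
                best_val, wait = vloss, 0
                best = [p.data.copy() for p in params]
            else:
                wait += 1
                if wait >= config.patience:
                    break
    if best is not None:
        for p, d in zip(params, best):
            p.data = d
    model.fitted = True
    return model


# ---------------------------------------------------------------------------
# unified posterior prediction
# ---------------------------------------------------------------------------

def predict_posterior(model, X_star: np.ndarray, S: int = 100,
                      seed: int = 0) -> PosteriorPrediction:
    """Posterior predictive for any fitted model in this package.

    Concrete dropout and flipout run S stochastic forward passes and report
    the per-point sample mean and standard deviation of the predicted mean
    (the epistemic component); the MDN and the GPs are closed form.
    """
    from .gp import GPModel, VGPModel, gp_posterior_predict, \
        vgp_posterior_predict

    if isinstance(model, GPModel):
        return gp_posterior_predict(model, X_star)
    if isinstance(model, VGPModel):
        return vgp_posterior_predict(model, X_star)
    if isinstance(model, MDNModel):
        if not model.fitted:
            raise RuntimeError("model is not fitted")
        pis, mus, sigmas = model.mixture_parameters(X_star)
        mom = np.array([mdn_predictive_moments(p, m, s)
                        for p, m, s in zip(pis, mus, sigmas)])
        sc = model.scaler
        return PosteriorPrediction(mean=mom[:, 0] * sc.y_std + sc.y_mean,
                                   std=mom[:, 1] * sc.y_std)
    if isinstance(model, BaselineMLP):
        if not model.fitted:
            raise RuntimeError("model is not fitted")
        sc = model.scaler
        mean = model._forward(sc.x(X_star)).data * sc.y_std + sc.y_mean
        return PosteriorPrediction(mean=mean, std=np.zeros_like(mean))
    if isinstance(model, (ConcreteDropoutNet, FlipoutNet)):
        if not model.fitted:
            raise RuntimeError("model is not fitted")
        if S < 2:
            raise ValueError("S must be >= 2 for sampled models")
        sc = model.scaler
        Xs = sc.x(X_star)
        draws = np.empty((S, Xs.shape[0]))
        for s_ix in range(S):
            rng = np.random.default_rng([seed, 3, s_ix])
            if isinstance(model, ConcreteDropoutNet):
                mean, _ = model._forward(Xs, rng)
            else:
                mean = model._forward(Xs, rng)
            draws[s_ix] = mean.data
        draws = draws * sc.y_std + sc.y_mean
        return PosteriorPrediction(mean=draws.mean(axis=0),
                                   std=draws.std(axis=0), samples=draws)
    raise TypeError(f"unsupported model type {type(model).__name__}")
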