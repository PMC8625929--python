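"""Concrete dropout, flipout and MDN: closed forms, training, prediction."""

import numpy as np
import pytest

import winsorbnn as w
from winsorbnn._autodiff import Tensor
from winsorbnn.nets import (_Scaler, ConcreteDropoutNet, FlipoutNet,
                            _flipout_kl, mdn_held_out_nll)

ARCH = w.NetworkArchitecture((32, 32))


# -- closed-form pieces ------------------------------------------------------

@pytest.mark.parametrize("p,expected", [
    (0.5, np.log(2)),
    (0.0, 0.0),
    (1.0, 0.0),
    (0.1, -(0.1 * np.log(0.1) + 0.9 * np.log(0.9))),
])
def test_bernoulli_entropy_values(p, expected):
    assert w.bernoulli_entropy(p) == pytest.approx(expected, abs=1e-10)


def test_bernoulli_entropy_maximal_at_half_and_domain():
    grid = np.linspace(0.01, 0.99, 50)
    assert np.argmax(w.bernoulli_entropy(grid)) == 24  # p = 0.5
    with pytest.raises(ValueError):
        w.bernoulli_entropy(1.2)


def test_concrete_mask_values_and_limits():
    assert w.concrete_dropout_mask(0.5, 1.0, 0.5) == pytest.approx(0.5)
    assert w.concrete_dropout_mask(0.5, 37.0, 0.5) == pytest.approx(0.5)
    # p=0.9, u=0.5, t=0.1 -> sigmoid(logit(0.9)/0.1) ~ sigmoid(21.97) ~ 1
    val = w.concrete_dropout_mask(0.9, 0.1, 0.5)
    assert val == pytest.approx(1.0, abs=1e-9)
    # temperature -> infinity flattens toward 1/2
    assert w.concrete_dropout_mask(0.9, 1e6, 0.5) == pytest.approx(0.5,
                                                                   abs=1e-5)
    # monotone in u and p
    u = np.linspace(0.1, 0.9, 9)
    assert np.all(np.diff(w.concrete_dropout_mask(0.3, 0.5, u)) > 0)
    p = np.linspace(0.1, 0.9, 9)
    assert np.all(np.diff(w.concrete_dropout_mask(p, 0.5, 0.4)) > 0)
    with pytest.raises(ValueError):
        w.concrete_dropout_mask(0.5, -1.0, 0.5)


def test_concrete_regularizer_hand_evaluated_single_layer():
    net = ConcreteDropoutNet(architecture=w.NetworkArchitecture((1,)),
                             n_features=2)
    # single hidden layer (2 -> 1) plus head (1 -> 2)
    W0 = np.array([[0.5], [-1.0]])
    W1 = np.array([[2.0, 0.0]])
    net.weights[0].data = W0
    net.weights[1].data = W1
    net.biases[0].data = np.array([0.3])
    net.biases[1].data = np.zeros(2)
    logit = np.log(0.2 / 0.8)
    net.p_logits[0].data = np.asarray(logit)
    net.p_logits[1].data = np.asarray(logit)
    N, l2 = 50, net.prior_lengthscale ** 2
    expected = 0.0
    for Wm, bm in ((W0, np.array([0.3])), (W1, np.zeros(2))):
        expected += l2 * (1 - 0.2) * np.sum(Wm ** 2) / (2 * N)
        expected += np.sum(bm ** 2) / (2 * N)
        expected -= Wm.size * w.bernoulli_entropy(0.2) / N
    got = w.concrete_dropout_regularizer(net, N)
    assert float(got.data) == pytest.approx(expected, abs=1e-10)
    with pytest.raises(ValueError):
        w.concrete_dropout_regularizer(net, 0)


def test_concrete_regularizer_monotone_in_weight_norm():
    net = ConcreteDropoutNet(architecture=w.NetworkArchitecture((4,)),
                             n_features=3)
    r0 = float(w.concrete_dropout_regularizer(net, 10).data)
    for W in net.weights:
        W.data = W.data * 3.0
    assert float(w.concrete_dropout_regularizer(net, 10).data) > r0


def test_gaussian_reparameterize():
    assert w.gaussian_reparameterize(1.3, 0.0, 0.0) == pytest.approx(1.3)
    assert w.gaussian_reparameterize(0.0, 0.0, 1.0) == \
        pytest.approx(np.log(2.0))
    rho = np.linspace(-20, 5, 40)
    assert np.all(np.logaddexp(0.0, rho) > 0)  # scale strictly positive


def test_flipout_perturbation_signs():
    rng = np.random.default_rng(0)
    dW = rng.normal(size=(3, 4))
    ones = np.ones(3), np.ones(4)
    np.testing.assert_array_equal(w.flipout_perturb(dW, *ones), dW)
    r = np.array([1.0, -1.0, 1.0])
    s = np.array([-1.0, 1.0, 1.0, -1.0])
    out = w.flipout_perturb(dW, r, s)
    np.testing.assert_allclose(np.abs(out), np.abs(dW))
    # mean over all four sign patterns of (r_j, s_k) is exactly zero
    acc = np.zeros_like(dW)
    for rj in (-1.0, 1.0):
        for sk in (-1.0, 1.0):
            acc += w.flipout_perturb(dW, np.full(3, rj), np.full(4, sk))
    np.testing.assert_array_equal(acc, np.zeros_like(dW))
    with pytest.raises(ValueError):
        w.flipout_perturb(dW, np.ones(4), np.ones(3))


def test_flipout_kl_hand_evaluated_and_zero_at_prior():
    net = FlipoutNet(architecture=w.NetworkArchitecture((1,)), n_features=1)
    # posterior = prior: mu = 0, softplus(rho) = 1  =>  KL = 0
    inv_softplus_one = np.log(np.e - 1.0)
    for mu, rho in zip((*net.W_mu, *net.b_mu), (*net.W_rho, *net.b_rho)):
        mu.data = np.zeros_like(mu.data)
        rho.data = np.full_like(rho.data, inv_softplus_one)
    assert float(_flipout_kl(net).data) == pytest.approx(0.0, abs=1e-10)
    # two-weight hand evaluation: KL = sum 0.5 (s^2 + m^2 - 1 - log s^2)
    net.W_mu[0].data = np.array([[0.4]])
    net.W_rho[0].data = np.array([[-1.0]])
    s2 = np.logaddexp(0.0, -1.0) ** 2
    expected = 0.5 * (s2 + 0.16 - 1 - np.log(s2))
    assert float(_flipout_kl(net).data) == pytest.approx(expected, abs=1e-10)
    assert float(_flipout_kl(net).data) >= 0


def test_variational_free_energy_validations(noisy_dataset):
    net = FlipoutNet(architecture=ARCH, n_features=4)
    X, y = noisy_dataset.rows("train")
    with pytest.raises(ValueError):
        w.variational_free_energy(net, (X, y), N=3)
    with pytest.raises(ValueError):
        w.variational_free_energy(net, (X[:0], y[:0]), N=100)


def test_flipout_reduces_batch_gradient_variance():
    """Across 100 minibatch draws, the variance of the flipout gradient
    estimate for the first-layer posterior mean is below that of the
    shared-perturbation estimate."""
    ds = w.split_dataset(w.make_tabular_regression(64, 3, 0.3, seed=5),
                         (1.0, 0.0, 0.0), seed=0)
    X, y = ds.rows("train")
    sc = _Scaler.fit(X, y)
    Xs, ys = sc.x(X), sc.y(y)
    net = FlipoutNet(architecture=w.NetworkArchitecture((8,)), n_features=3)
    for rho in (*net.W_rho, *net.b_rho):
        rho.data = np.full_like(rho.data, 0.0)  # sizeable posterior scale

    def grads(use_flipout):
        out = []
        for b in range(100):
            rng = np.random.default_rng([9, b])
            for p in net.parameters():
                p.grad = None
            loss = w.variational_free_energy(net, (Xs, ys), N=len(ys),
                                             rng=rng,
                                             use_flipout=use_flipout)
            loss.backward()
            out.append(net.W_mu[0].grad.copy())
        return np.var(np.stack(out), axis=0).mean()

    assert grads(True) < grads(False)


@pytest.mark.parametrize("tag,n_layers,expected", [
    ("all", 7, list(range(7))),
    ("early5", 7, [0, 1, 2, 3, 4]),
    ("mid5", 7, [1, 2, 3, 4, 5]),
    ("final5", 7, [2, 3, 4, 5, 6]),
])
def test_flipout_layer_subsets(tag, n_layers, expected):
    assert w.flipout_layer_indices(n_layers, tag) == expected


def test_flipout_mid5_carries_exactly_five_variational_layers():
    net = FlipoutNet(architecture=w.NetworkArchitecture((8,) * 6),
                     n_features=3, flipout_layers="mid5")
    assert net.n_variational_layers == 5
    with pytest.raises(ValueError):
        w.flipout_layer_indices(7, "odd5")


# -- MDN closed forms --------------------------------------------------------

def test_mdn_nll_standard_normal_and_collapse():
    val = w.mdn_negative_log_likelihood([1.0], [0.0], [1.0], 0.0)
    assert val == pytest.approx(0.5 * np.log(2 * np.pi), abs=1e-12)
    # identical components collapse to the single-component value
    val3 = w.mdn_negative_log_likelihood([1 / 3] * 3, [0.2] * 3, [0.7] * 3,
                                         0.5)
    val1 = w.mdn_negative_log_likelihood([1.0], [0.2], [0.7], 0.5)
    assert val3 == pytest.approx(val1, abs=1e-10)
    with pytest.raises(ValueError):
        w.mdn_negative_log_likelihood([1.0], [0.0], [-1.0], 0.0)


def test_mdn_nll_matches_naive_density_oracle():
    rng = np.random.default_rng(2)
    for _ in range(30):
        K = rng.integers(1, 5)
        raw = rng.uniform(0.2, 1.0, size=K)
        pi = raw / raw.sum()
        mu = rng.normal(size=K) * 3
        sigma = rng.uniform(0.3, 2.0, size=K)
        y = rng.normal() * 3
        dens = np.sum(pi * np.exp(-0.5 * ((y - mu) / sigma) ** 2)
                      / (sigma * np.sqrt(2 * np.pi)))
        assert w.mdn_negative_log_likelihood(pi, mu, sigma, y) == \
            pytest.approx(-np.log(dens), abs=1e-8)


def test_mdn_predictive_moments():
    mean, std = w.mdn_predictive_moments([0.5, 0.5], [-1.0, 1.0], [1.0, 1.0])
    assert mean == pytest.approx(0.0)
    assert std ** 2 == pytest.approx(2.0)
    mean1, std1 = w.mdn_predictive_moments([1.0], [0.7], [0.4])
    assert (mean1, std1) == (pytest.approx(0.7), pytest.approx(0.4))


# -- training ----------------------------------------------------------------

def test_concrete_dropout_training_contract(smooth_dataset):
    cfg = w.TrainConfig(epochs=300, seed=0)
    net = w.fit_concrete_dropout(smooth_dataset, ARCH, cfg)
    net2 = w.fit_concrete_dropout(smooth_dataset, ARCH, cfg)
    np.testing.assert_array_equal(net.dropout_probabilities,
                                  net2.dropout_probabilities)
    assert np.all((net.dropout_probabilities > 0.01)
                  & (net.dropout_probabilities < 0.99))
    Xte, yte = smooth_dataset.rows("test")
    pred = w.predict_posterior(net, Xte, S=100, seed=0)
    r2 = 1 - np.mean((yte - pred.mean) ** 2) / yte.var()
    assert r2 > 0.8


def test_flipout_training_deterministic(noisy_dataset):
    cfg = w.TrainConfig(epochs=150, seed=3)
    a = w.fit_flipout(noisy_dataset, ARCH, "all", cfg)
    b = w.fit_flipout(noisy_dataset, ARCH, "all", cfg)
    for pa, pb in zip(a.parameters(), b.parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)


def test_mdn_k1_recovers_noise_scale():
    ds = w.split_dataset(w.make_tabular_regression(2000, 3, noise_sd=0.5,
                                                   seed=6),
                         (0.7, 0.1, 0.2), seed=0)
    model = w.fit_mdn(ds, ARCH, K=1, config=w.TrainConfig(epochs=400,
                                                          seed=0))
    Xte, yte = ds.rows("test")
    _, _, sigma = model.mixture_parameters(Xte)
    est_sd = np.median(sigma) * model.scaler.y_std
    assert abs(est_sd / 0.5 - 1) < 0.2


def test_mdn_recovers_two_modes(bimodal_dataset):
    model = w.fit_mdn(bimodal_dataset, ARCH, K=2,
                      config=w.TrainConfig(epochs=300, seed=0))
    model2 = w.fit_mdn(bimodal_dataset, ARCH, K=2,
                       config=w.TrainConfig(epochs=300, seed=0))
    for pa, pb in zip(model.parameters(), model2.parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)   # determinism
    _, mus, _ = model.mixture_parameters(np.array([[0.0]]))
    means = np.sort(mus[0] * model.scaler.y_std + model.scaler.y_mean)
    assert means[0] < -1.0 and means[1] > 1.0   # planted offsets +-2


def test_mdn_multi_component_beats_single_on_bimodal(bimodal_dataset):
    cfg = w.TrainConfig(epochs=300, seed=0)
    m1 = w.fit_mdn(bimodal_dataset, ARCH, K=1, config=cfg)
    m2 = w.fit_mdn(bimodal_dataset, ARCH, K=2, config=cfg)
    Xte, yte = bimodal_dataset.rows("test")
    assert mdn_held_out_nll(m2, Xte, yte) < mdn_held_out_nll(m1, Xte, yte)


# -- unified prediction ------------------------------------------------------

def test_predict_posterior_contracts(smooth_dataset):
    cfg = w.TrainConfig(epochs=60, seed=0)
    net = w.fit_concrete_dropout(smooth_dataset, ARCH, cfg)
    Xte = smooth_dataset.rows("test")[0][:5]
    with pytest.raises(ValueError):
        w.predict_posterior(net, Xte, S=1, seed=0)
    a = w.predict_posterior(net, Xte, S=50, seed=0)
    b = w.predict_posterior(net, Xte, S=50, seed=0)
    np.testing.assert_array_equal(a.mean, b.mean)   # seeded determinism
    assert a.samples.shape == (50, 5)
    assert np.all(a.std >= 0)


def test_monte_carlo_error_shrinks_with_sample_count(smooth_dataset):
    net = w.fit_concrete_dropout(smooth_dataset, ARCH,
                                 w.TrainConfig(epochs=60, seed=0))
    Xte = smooth_dataset.rows("test")[0][:3]
    ref = w.predict_posterior(net, Xte, S=1600, seed=0).mean
    err_small = np.abs(w.predict_posterior(net, Xte, S=25, seed=0).mean - ref)
    err_big = np.abs(w.predict_posterior(net, Xte, S=400, seed=0).mean - ref)
    assert err_big.mean() < err_small.mean()


def test_mdn_prediction_is_closed_form_and_repeatable(bimodal_dataset):
    model = w.fit_mdn(bimodal_dataset, ARCH, K=2,
                      config=w.TrainConfig(epochs=60, seed=0))
    Xte = bimodal_dataset.rows("test")[0][:4]
    a = w.predict_posterior(model, Xte)
    b = w.predict_posterior(model, Xte)
    np.testing.assert_array_equal(a.mean, b.mean)
    np.testing.assert_array_equal(a.std, b.std)


def test_baseline_mlp_predicts_deterministically(noisy_dataset):
    model = w.fit_baseline_mlp(noisy_dataset, ARCH,
                               w.TrainConfig(epochs=100, seed=0))
    Xte = noisy_dataset.rows("test")[0]
    pred = w.predict_posterior(model, Xte)
    assert np.all(pred.std == 0)
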