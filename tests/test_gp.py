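"""Exact and sparse variational GP: oracles, bounds, recovery, contracts."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import winsorbnn as w
from winsorbnn.gp import GPModel, VGPModel


# -- RBF kernel --------------------------------------------------------------

def test_rbf_diagonal_symmetry_and_closed_form():
    X = np.random.default_rng(0).normal(size=(6, 3))
    K = w.rbf_kernel(X, X, 1.0, 1.0)
    np.testing.assert_allclose(np.diag(K), 1.0)
    np.testing.assert_allclose(K, K.T)
    # ||x - x'|| = sqrt(2) at unit amplitude/lengthscale -> exp(-1)
    a = np.array([[0.0, 0.0]])
    b = np.array([[1.0, 1.0]])
    assert w.rbf_kernel(a, b, 1.0, 1.0)[0, 0] == pytest.approx(np.exp(-1.0))
    with pytest.raises(ValueError):
        w.rbf_kernel(a, b, -1.0, 1.0)
    with pytest.raises(ValueError):
        w.rbf_kernel(a, np.zeros((1, 3)), 1.0, 1.0)


# -- log marginal likelihood -------------------------------------------------

def test_lml_single_point_standard_normal():
    m = GPModel(amplitude=1.0, lengthscale=1.0, noise_variance=0.0,
                mean_constant=0.0, jitter=0.0)
    # n=1, Sigma=[[1]], y=[0] -> -log(2 pi)/2
    val = w.gp_log_marginal_likelihood(m, np.zeros((1, 1)), np.zeros(1))
    assert val == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-9)


def test_lml_matches_dense_normal_density_oracle():
    rng = np.random.default_rng(3)
    for _ in range(5):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        m = GPModel(amplitude=1.3, lengthscale=0.8, noise_variance=0.3,
                    mean_constant=0.2, jitter=0.0)
        K = w.rbf_kernel(X, X, 1.3, 0.8) + 0.3 * np.eye(5)
        oracle = multivariate_normal(mean=0.2 * np.ones(5), cov=K).logpdf(y)
        assert w.gp_log_marginal_likelihood(m, X, y) == \
            pytest.approx(oracle, abs=1e-8)


def test_lml_invariant_under_row_permutation():
    rng = np.random.default_rng(4)
    X, y = rng.normal(size=(8, 2)), rng.normal(size=8)
    m = GPModel(amplitude=1.0, lengthscale=1.2, noise_variance=0.1)
    perm = rng.permutation(8)
    assert w.gp_log_marginal_likelihood(m, X, y) == \
        pytest.approx(w.gp_log_marginal_likelihood(m, X[perm], y[perm]),
                      abs=1e-9)


# -- fitting -----------------------------------------------------------------

def test_fit_deterministic_and_two_trainable_parameters(gp_draw):
    X, y = gp_draw
    ds = w.Dataset(X, y, np.full(len(y), "train"), "tabular", ["x0"], 0)
    a = w.fit_exact_gp(ds, w.GPConfig(standardize=False))
    b = w.fit_exact_gp(ds, w.GPConfig(standardize=False))
    assert (a.amplitude, a.lengthscale) == (b.amplitude, b.lengthscale)
    assert a.n_trainable_parameters == 2


def test_hyperparameter_recovery_on_simulated_gp_draw(gp_draw):
    """ML estimates of amplitude/lengthscale land within 25% of the
    generating values (1.5, 2.0) on a 200-point draw."""
    X, y = gp_draw
    ds = w.Dataset(X, y, np.full(len(y), "train"), "tabular", ["x0"], 0)
    gp = w.fit_exact_gp(ds, w.GPConfig(standardize=False))
    assert abs(gp.amplitude / 1.5 - 1) < 0.25
    assert abs(gp.lengthscale / 2.0 - 1) < 0.25


def test_degenerate_inputs_signalled():
    from winsorbnn.gp import DegenerateInput
    X = np.ones((40, 2))
    ds = w.Dataset(X, np.arange(40.0), np.full(40, "train"), "tabular",
                   ["a", "b"], 0)
    with pytest.raises(DegenerateInput):
        w.fit_exact_gp(ds)


# -- posterior prediction ----------------------------------------------------

def _toy_model(noise=0.0):
    X = np.array([[0.0], [1.0]])
    y = np.array([1.0, -1.0])
    return GPModel(amplitude=1.0, lengthscale=1.0, noise_variance=noise,
                   mean_constant=0.0, X_train=X, y_train=y, jitter=1e-12)


def test_noiseless_gp_interpolates_training_points():
    m = _toy_model(noise=0.0)
    pred = w.gp_posterior_predict(m, m.X_train)
    np.testing.assert_allclose(pred.mean, m.y_train, atol=1e-6)
    np.testing.assert_allclose(pred.std, 0.0, atol=1e-4)


def test_prior_reversion_far_from_data():
    m = _toy_model(noise=0.0)
    m.mean_constant = 0.7
    pred = w.gp_posterior_predict(m, np.array([[500.0]]))
    assert pred.mean[0] == pytest.approx(0.7, abs=1e-8)
    assert pred.std[0] ** 2 == pytest.approx(1.0, abs=1e-8)  # amplitude^2


def test_posterior_matches_hand_conditioning_oracle():
    """2 train / 1 test: closed-form Gaussian conditioning by hand."""
    m = _toy_model(noise=0.1)
    xs = np.array([[0.4]])
    K = w.rbf_kernel(m.X_train, m.X_train, 1.0, 1.0) + 0.1 * np.eye(2)
    ks = w.rbf_kernel(m.X_train, xs, 1.0, 1.0)
    mean_o = (ks.T @ np.linalg.solve(K, m.y_train))[0]
    var_o = (1.0 - ks.T @ np.linalg.solve(K, ks) + 0.1)[0, 0]
    pred = w.gp_posterior_predict(m, xs)
    assert pred.mean[0] == pytest.approx(float(mean_o), abs=1e-8)
    assert pred.std[0] == pytest.approx(float(np.sqrt(var_o)), abs=1e-8)


def test_unfitted_model_raises():
    m = GPModel(amplitude=1.0, lengthscale=1.0)
    with pytest.raises(RuntimeError):
        w.gp_posterior_predict(m, np.zeros((1, 1)))


# -- sparse variational GP ---------------------------------------------------

def _vgp_at(X, amplitude=1.5, lengthscale=2.0, beta=100.0, q_mu=None,
            q_L=None, jitter=1e-10):
    mq = np.zeros(X.shape[0]) if q_mu is None else q_mu
    L = np.eye(X.shape[0]) if q_L is None else q_L
    return VGPModel(Z=X.copy(), q_mu=mq, q_L=L, amplitude=amplitude,
                    lengthscale=lengthscale, beta=beta, jitter=jitter)


def test_collapsed_bound_equals_exact_lml_when_inducing_at_data(gp_draw):
    X, y = gp_draw
    vm = _vgp_at(X)
    exact = GPModel(amplitude=1.5, lengthscale=2.0, noise_variance=1e-2,
                    mean_constant=0.0)
    assert w.svgp_collapsed_bound(vm, X, y) == pytest.approx(
        w.gp_log_marginal_likelihood(exact, X, y), abs=1e-3 * abs(
            w.gp_log_marginal_likelihood(exact, X, y)))


def test_collapsed_bound_equals_exact_lml_small_problem():
    rng = np.random.default_rng(5)
    X, y = rng.normal(size=(12, 2)), rng.normal(size=12)
    vm = _vgp_at(X, amplitude=1.1, lengthscale=0.9, beta=5.0)
    exact = GPModel(amplitude=1.1, lengthscale=0.9, noise_variance=0.2,
                    mean_constant=0.0, jitter=1e-12)
    assert w.svgp_collapsed_bound(vm, X, y) == pytest.approx(
        w.gp_log_marginal_likelihood(exact, X, y), abs=1e-6)


def test_elbo_never_exceeds_exact_lml():
    rng = np.random.default_rng(6)
    for trial in range(5):
        X, y = rng.normal(size=(15, 2)), rng.normal(size=15)
        Z = X[rng.choice(15, size=6, replace=False)]
        vm = VGPModel(Z=Z, q_mu=rng.normal(size=6) * 0.1,
                      q_L=np.eye(6) * 0.5, amplitude=1.0, lengthscale=1.0,
                      beta=4.0)
        exact = GPModel(amplitude=1.0, lengthscale=1.0, noise_variance=0.25,
                        mean_constant=0.0)
        assert w.svgp_elbo(vm, X, y) <= \
            w.gp_log_marginal_likelihood(exact, X, y) + 1e-9


def test_kl_zero_when_posterior_equals_prior():
    rng = np.random.default_rng(7)
    X, y = rng.normal(size=(10, 1)), rng.normal(size=10)
    Z = X[:4]
    Kmm = w.rbf_kernel(Z, Z, 1.0, 1.0) + 1e-8 * np.eye(4)
    vm = VGPModel(Z=Z, q_mu=np.zeros(4), q_L=np.linalg.cholesky(Kmm),
                  amplitude=1.0, lengthscale=1.0, beta=2.0, jitter=1e-8)
    parts = w.svgp_elbo(vm, X, y, return_parts=True)
    assert parts["kl"] == pytest.approx(0.0, abs=1e-6)
    assert parts["elbo"] == pytest.approx(
        parts["fit"] + parts["trace"] + parts["s_term"], abs=1e-9)


def test_fit_vgp_ascends_deterministically_and_tracks_exact_gp():
    ds = w.split_dataset(w.make_tabular_regression(150, 2, 0.2, seed=8),
                         (0.7, 0.1, 0.2), seed=0)
    cfg = w.VGPConfig(iters=200, seed=0)
    n_train = int(ds.mask("train").sum())
    vg = w.fit_variational_gp(ds, m_ind=n_train, config=cfg)
    vg2 = w.fit_variational_gp(ds, m_ind=n_train, config=cfg)
    assert vg.to_dict() == vg2.to_dict()                 # determinism
    assert vg.elbo_trace[-1] > vg.elbo_trace[0]          # ascent contract
    Xte, yte = ds.rows("test")
    mse_v = np.mean((w.vgp_posterior_predict(vg, Xte).mean - yte) ** 2)
    gp = w.fit_exact_gp(ds)
    mse_g = np.mean((w.gp_posterior_predict(gp, Xte).mean - yte) ** 2)
    # with inducing points at every training input the sparse model tracks
    # the exact GP on a smooth problem
    assert mse_v <= 1.1 * mse_g + 1e-3
    with pytest.raises(ValueError):
        w.fit_variational_gp(ds, m_ind=0)


def test_vgp_predictive_variance_nonnegative():
    ds = w.split_dataset(w.make_tabular_regression(100, 2, 0.3, seed=9),
                         (0.7, 0.1, 0.2), seed=0)
    vg = w.fit_variational_gp(ds, m_ind=20, config=w.VGPConfig(iters=100,
                                                               seed=1))
    pred = w.vgp_posterior_predict(vg, ds.rows("test")[0])
    assert np.all(pred.std >= 0)
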