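import numpy as np
import pytest
from scipy.optimize import minimize

import metpath as mp
from metpath.survival import cox_partial_loglik, cox_partial_loglik_grad

from conftest import make_surv


def newton_unpenalized_cox(X, surv):
    """Independent oracle: maximize the partial likelihood directly."""

    def nll(b):
        return -cox_partial_loglik(X @ b, surv)

    def grad(b):
        return -X.T @ cox_partial_loglik_grad(X @ b, surv)

    res = minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
                   options={"gtol": 1e-10})
    return res.x


def simulate_linear_cox(n, p, beta, seed, censor=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    T = rng.exponential(1.0 / np.exp(X @ beta))
    event = np.ones(n, dtype=int)
    if censor > 0:
        C = rng.exponential(np.quantile(T, 1 - censor) * 2, size=n)
        event = (T <= C).astype(int)
        T = np.minimum(T, C)
    return X, make_surv(T, event)


class TestPenalizedCox:
    def test_lambda_zero_matches_newton_oracle(self):
        X, surv = simulate_linear_cox(50, 3, np.array([1.0, -1.0, 0.5]), seed=0)
        res = mp.fit_penalized_cox(X, surv, lambda_=0.0)
        oracle = newton_unpenalized_cox(X, surv)
        np.testing.assert_allclose(res.beta, oracle, atol=1e-4)

    def test_large_lambda_zeroes_everything(self):
        X, surv = simulate_linear_cox(60, 5, np.array([1.0, 0, 0, 0, 0]), seed=1)
        res = mp.fit_penalized_cox(X, surv, alpha=1.0, lambda_=1e4)
        assert np.all(res.beta == 0)

    def test_l1_norm_decreases_along_increasing_lambda(self):
        X, surv = simulate_linear_cox(80, 6, np.array([1.0, -0.5, 0, 0, 0.8, 0]), seed=2)
        lams = [0.001, 0.01, 0.05, 0.2]
        norms = [
            np.abs(mp.fit_penalized_cox(X, surv, alpha=1.0, lambda_=l).beta).sum()
            for l in lams
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_true_features_have_largest_coefficients(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            beta = np.zeros(20)
            beta[[2, 9, 17]] = [1.0, -1.0, 1.0]
            X, surv = simulate_linear_cox(300, 20, beta, seed=seed)
            res = mp.fit_penalized_cox(X, surv, alpha=1.0, lambda_rule="lambda_1se", seed=seed)
            top3 = set(np.argsort(-np.abs(res.beta))[:3])
            hits += top3 == {2, 9, 17}
        assert hits / n_seeds >= 0.9

    def test_lambda_1se_at_least_lambda_min(self):
        X, surv = simulate_linear_cox(100, 10, np.r_[np.ones(2), np.zeros(8)], seed=3)
        model = mp.PenalizedCox(X, surv, alpha=1.0)
        r_min = model.fit(lambda_rule="lambda_min", seed=0)
        r_1se = model.fit(lambda_rule="lambda_1se", seed=0)
        assert r_1se.lambda_ >= r_min.lambda_
        assert len(r_1se.nonzero_features) <= len(r_min.nonzero_features)

    def test_invalid_alpha_error(self):
        X, surv = simulate_linear_cox(20, 2, np.zeros(2), seed=4)
        with pytest.raises(ValueError, match="alpha"):
            mp.PenalizedCox(X, surv, alpha=1.5)

    def test_ridge_shrinks_but_keeps_all(self):
        X, surv = simulate_linear_cox(60, 4, np.array([1.0, -1.0, 0.5, 0.0]), seed=5)
        res = mp.fit_penalized_cox(X, surv, alpha=0.0, lambda_=0.5)
        unpen = newton_unpenalized_cox(X, surv)
        assert np.all(res.beta != 0)
        assert np.abs(res.beta).sum() < np.abs(unpen).sum()


class TestCoxNeuralNet:
    def test_cost_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        n, p, h = 15, 4, 3
        X = rng.normal(size=(n, p))
        surv = make_surv(rng.exponential(size=n), np.ones(n, dtype=int))
        model = mp.CoxNeuralNet(X, surv, hidden_size=h, activation="tanh", lambda_=0.1)
        flat = rng.normal(size=h * p + h + h) * 0.5
        _, g = model.cost_grad(flat)
        eps = 1e-6
        for i in range(len(flat)):
            e = np.zeros(len(flat))
            e[i] = eps
            fd = (model.cost_grad(flat + e)[0] - model.cost_grad(flat - e)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, abs=1e-5)

    def test_identity_activation_matches_linear_cox(self):
        X, surv = simulate_linear_cox(120, 5, np.array([1.0, -1.0, 0.5, 0.0, 0.8]), seed=6)
        tr, te = np.arange(80), np.arange(80, 120)
        lin = mp.fit_penalized_cox(X[tr], surv.subset(tr), lambda_=0.0)
        nn = mp.fit_coxnnet(
            X[tr], surv.subset(tr), hidden_size=5, activation="identity", lambda_=0.0,
            config=mp.CoxnnetConfig(learning_rate=0.05, max_iter=3000),
        )
        c_lin = mp.c_index(lin.predict(X[te]), surv.subset(te))
        c_nn = mp.c_index(nn.predict(X[te]), surv.subset(te))
        assert abs(c_lin - c_nn) <= 0.03

    def test_huge_lambda_shrinks_weights_to_zero(self):
        X, surv = simulate_linear_cox(40, 3, np.array([1.0, 0.0, -1.0]), seed=7)
        nn = mp.fit_coxnnet(X, surv, hidden_size=2, lambda_=1e6)
        assert np.linalg.norm(nn.beta) < 1e-3
        assert np.linalg.norm(nn.W) < 1e-3
        pi = nn.predict(X)
        assert np.ptp(pi) < 1e-6

    @pytest.mark.parametrize("algorithm", ["standard", "momentum", "nesterov"])
    def test_descent_variants_reduce_cost(self, algorithm):
        X, surv = simulate_linear_cox(60, 4, np.array([1.0, -1.0, 0.5, 0.0]), seed=8)
        nn = mp.fit_coxnnet(
            X, surv, hidden_size=3,
            config=mp.CoxnnetConfig(algorithm=algorithm, max_iter=500),
        )
        assert nn.cost_history[-1] < nn.cost_history[0]

    def test_select_lambda_returns_candidate(self):
        X, surv = simulate_linear_cox(60, 4, np.array([1.0, -1.0, 0.0, 0.0]), seed=9)
        model = mp.CoxNeuralNet(X, surv, hidden_size=2)
        lam = model.select_lambda(
            [0.0, 0.1], cv_folds=3,
            config=mp.CoxnnetConfig(max_iter=200, min_iter=50),
        )
        assert lam in (0.0, 0.1)


class TestPrognosisIndex:
    def test_linear_dot_product(self):
        X, surv = simulate_linear_cox(10, 2, np.zeros(2), seed=10)
        res = mp.fit_penalized_cox(X, surv, lambda_=0.0)
        res.beta = np.array([1.0, -1.0])
        assert mp.prognosis_index(res, np.array([[2.0, 3.0]]))[0] == pytest.approx(-1.0)

    def test_batch_concatenation(self):
        X, surv = simulate_linear_cox(30, 3, np.array([1.0, 0.0, -0.5]), seed=11)
        res = mp.fit_penalized_cox(X, surv, lambda_=0.0)
        whole = res.predict(X)
        parts = np.concatenate([res.predict(X[:10]), res.predict(X[10:])])
        np.testing.assert_allclose(whole, parts)


class TestEvaluateProgosis:
    def test_perfectly_informative_pi(self):
        rng = np.random.default_rng(12)
        n = 200
        t = np.sort(rng.exponential(size=n))
        surv = make_surv(t, np.ones(n, dtype=int))
        pi = -t  # perfect ranking
        from metpath.prognosis import _evaluate_pi

        ev = _evaluate_pi(pi, surv, "median")
        assert ev.c_index == 1.0
        assert ev.logrank_p < 0.001

    def test_out_of_fold_pi_covers_every_sample(self):
        X, surv = simulate_linear_cox(60, 4, np.array([1.0, -1.0, 0.0, 0.0]), seed=13)
        res = mp.fit_penalized_cox(X, surv, lambda_=0.05)
        ev = mp.evaluate_prognosis(res, X, surv, cv_folds=3, seed=0)
        assert len(ev.pi) == 60
        assert np.isfinite(ev.pi).all()

    def test_evaluation_summary_fields(self, surv_dataset):
        _, _, surv, Z = surv_dataset
        res = mp.fit_penalized_cox(Z, surv, alpha=1.0, lambda_rule="lambda_min", seed=0)
        ev = res.evaluate(Z, surv)
        assert 0 <= ev.c_index <= 1
        assert ev.logrank_p <= 1
        assert set(ev.km.group) <= {"high", "low"}
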