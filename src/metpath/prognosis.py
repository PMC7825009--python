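"""Prognosis models: penalized Cox regression and a Cox neural network.

Both are exposed statsmodels-style: a Model object is built from a
feature matrix (metabolite intensities or pathway dysregulation
scores) and a :class:`~metpath.io.SurvivalData`; ``fit()`` returns a
Results object carrying the estimates, the cross-validation path and
evaluation helpers.  The per-sample prognosis index (PI) is the log
hazard ratio theta: ``X @ beta`` for the linear model and
``G(W x + b)' beta`` for the neural model.  The baseline hazard is
never estimated — PI ranking, the concordance index, the log-rank test
and Kaplan-Meier curves on PI-defined groups only need theta.

The elastic-net path (penalty lambda * [alpha ||b||_1 +
(1-alpha) ||b||_2^2 / 2]) is solved by scikit-survival's coordinate
descent for alpha > 0 and by lifelines' Newton solver for the ridge
and unpenalized cases; the cross-validated partial likelihood
(Verweij & van Houwelingen) used to pick ``lambda.min``/``lambda.1se``
is computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SurvivalData
from .survival import (
    c_index,
    cox_partial_loglik,
    cox_partial_loglik_grad,
    dichotomize,
    km_table,
    logrank_test,
)

__all__ = [
    "PenalizedCox",
    "PenalizedCoxResults",
    "CoxNeuralNet",
    "CoxNeuralNetResults",
    "PrognosisEvaluation",
    "fit_penalized_cox",
    "fit_coxnnet",
    "prognosis_index",
    "evaluate_prognosis",
]


# --------------------------------------------------------------------------
# shared helpers


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


def _cv_fold_indices(n: int, cv_folds: int, events: np.ndarray, seed: int) -> list[np.ndarray]:
    """Event-stratified fold assignment so every fold sees events."""
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    for grp in (np.where(events == 1)[0], np.where(events == 0)[0]):
        perm = rng.permutation(grp)
        folds[perm] = np.arange(len(perm)) % cv_folds
    return [np.where(folds == k)[0] for k in range(cv_folds)]


def _cv_pl(theta_full: np.ndarray, surv: SurvivalData, train_idx: np.ndarray) -> float:
    """Verweij-van Houwelingen cross-validated partial likelihood term."""
    pl_all = cox_partial_loglik(theta_full, surv)
    tr = SurvivalData(
        [surv.sample_ids[i] for i in train_idx], surv.time[train_idx], surv.event[train_idx]
    )
    pl_tr = cox_partial_loglik(theta_full[train_idx], tr)
    return pl_all - pl_tr


@dataclass
class PrognosisEvaluation:
    """PI-based evaluation: risk groups, concordance, log-rank, KM tables."""

    pi: np.ndarray
    groups: np.ndarray
    c_index: float
    logrank_stat: float
    logrank_p: float
    km: pd.DataFrame
    dichotomize_method: str = "median"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["c_index", "logrank_stat", "logrank_p"],
                "value": [self.c_index, self.logrank_stat, self.logrank_p],
            }
        )


def _evaluate_pi(
    pi: np.ndarray, surv: SurvivalData, method: str = "median"
) -> PrognosisEvaluation:
    groups = dichotomize(pi, surv, method=method)
    stat, p = logrank_test(groups, surv)
    return PrognosisEvaluation(
        pi=pi,
        groups=groups,
        c_index=c_index(pi, surv),
        logrank_stat=stat,
        logrank_p=p,
        km=km_table(surv, groups),
        dichotomize_method=method,
    )


# --------------------------------------------------------------------------
# penalized linear Cox


class PenalizedCox:
    """Elastic-net penalized Cox proportional-hazards model.

    Parameters
    ----------
    X : DataFrame or ndarray
        n x p feature matrix (metabolite or pathway level).
    surv : SurvivalData
        Aligned survival outcomes.
    alpha : float
        Elastic-net mixing in [0, 1]: 1 = Lasso (default), 0 = Ridge.
    """

    def __init__(self, X, surv: SurvivalData, alpha: float = 1.0):
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        self.X = _as_frame(X)
        if len(self.X) != len(surv):
            raise ValueError("X and survival data are not aligned")
        self.surv = surv
        self.alpha = float(alpha)

    # -- solvers -----------------------------------------------------------

    def _solve_unpenalized(self) -> np.ndarray:
        from lifelines import CoxPHFitter

        df = self.X.copy()
        df["_time"], df["_event"] = self.surv.time, self.surv.event
        cph = CoxPHFitter(penalizer=0.0)
        cph.fit(df, duration_col="_time", event_col="_event")
        return cph.params_.reindex(self.X.columns).to_numpy()

    def _solve_ridge(self, lam: float, X: pd.DataFrame, surv: SurvivalData) -> np.ndarray:
        from lifelines import CoxPHFitter

        df = X.copy()
        df["_time"], df["_event"] = surv.time, surv.event
        cph = CoxPHFitter(penalizer=lam, l1_ratio=0.0)
        cph.fit(df, duration_col="_time", event_col="_event")
        return cph.params_.reindex(X.columns).to_numpy()

    def _coxnet_path(self, X: pd.DataFrame, surv: SurvivalData, lambdas: np.ndarray | None):
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        y = Surv.from_arrays(surv.event.astype(bool), surv.time)
        model = CoxnetSurvivalAnalysis(
            l1_ratio=self.alpha,
            alphas=None if lambdas is None else list(lambdas),
            n_alphas=100,
            alpha_min_ratio=0.001,
            max_iter=100000,
        )
        model.fit(X.to_numpy(), y)
        alphas_ret = np.asarray(model.alphas_)
        coefs = np.asarray(model.coef_)  # p x n_alphas
        if lambdas is not None and len(alphas_ret) != len(lambdas):
            # the solver may truncate the path; carry the last computed
            # coefficients forward for the smaller requested lambdas
            # (the glmnet cross-validation convention)
            out = np.empty((coefs.shape[0], len(lambdas)))
            for j, lam in enumerate(lambdas):
                k = int(np.argmin(np.abs(alphas_ret - lam)))
                if alphas_ret[k] < lam and k > 0:
                    k -= 1
                out[:, j] = coefs[:, k]
            return np.asarray(lambdas, dtype=float), out
        return alphas_ret, coefs

    def _ridge_lambda_grid(self) -> np.ndarray:
        # mirror the elastic-net convention: 100 log-spaced values down to
        # 0.001 * lambda_max, with lambda_max taken from the alpha=0.01 path
        Xs = (self.X - self.X.mean()) / self.X.std(ddof=1).replace(0, 1.0)
        g = cox_partial_loglik_grad(np.zeros(len(self.surv)), self.surv)
        lam_max = np.abs(Xs.to_numpy().T @ g).max() / max(self.alpha, 0.01) / len(self.surv)
        return np.geomspace(lam_max, 0.001 * lam_max, 100)

    # -- public API --------------------------------------------------------

    def fit(
        self,
        lambda_rule: str = "lambda_1se",
        cv_folds: int = 5,
        seed: int = 0,
        lambda_: float | None = None,
    ) -> "PenalizedCoxResults":
        """Fit the model, selecting lambda by cross-validation.

        ``lambda_rule`` is ``'lambda_min'`` (best mean CV partial
        likelihood) or ``'lambda_1se'`` (largest lambda within one
        standard error of the best; the default, favouring sparser
        models).  Passing ``lambda_`` skips CV and fits at that value;
        ``lambda_=0`` is the unpenalized Newton fit.
        """
        if lambda_ is not None:
            if lambda_ == 0:
                beta = self._solve_unpenalized()
            elif self.alpha == 0:
                beta = self._solve_ridge(lambda_, self.X, self.surv)
            else:
                _, coefs = self._coxnet_path(self.X, self.surv, np.array([lambda_]))
                beta = coefs[:, 0]
            return PenalizedCoxResults(self, beta, float(lambda_), "fixed", None)

        if lambda_rule not in {"lambda_min", "lambda_1se"}:
            raise ValueError(f"unknown lambda rule {lambda_rule!r}")

        if self.alpha == 0:
            lambdas = self._ridge_lambda_grid()
            full_coefs = np.column_stack(
                [self._solve_ridge(l, self.X, self.surv) for l in lambdas]
            )
            fold_fit = lambda Xtr, str_, lams: np.column_stack(
                [self._solve_ridge(l, Xtr, str_) for l in lams]
            )
        else:
            lambdas, full_coefs = self._coxnet_path(self.X, self.surv, None)
            fold_fit = lambda Xtr, str_, lams: self._coxnet_path(Xtr, str_, lams)[1]

        folds = _cv_fold_indices(len(self.surv), cv_folds, self.surv.event, seed)
        scores = np.full((cv_folds, len(lambdas)), np.nan)
        Xnp = self.X.to_numpy()
        for k, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(self.surv)), test_idx)
            str_ = self.surv.subset(train_idx)
            coefs_k = fold_fit(self.X.iloc[train_idx], str_, lambdas)
            for j in range(len(lambdas)):
                theta = Xnp @ coefs_k[:, j]
                scores[k, j] = _cv_pl(theta, self.surv, train_idx)
        deviance = -2.0 * scores
        mean_dev = deviance.mean(axis=0)
        se_dev = deviance.std(axis=0, ddof=1) / np.sqrt(cv_folds)
        j_min = int(np.argmin(mean_dev))
        if lambda_rule == "lambda_min":
            j_sel = j_min
        else:
            bar = mean_dev[j_min] + se_dev[j_min]
            within = np.where(mean_dev <= bar)[0]
            j_sel = int(within[np.argmax(lambdas[within])])
        cv_path = pd.DataFrame(
            {"lambda": lambdas, "mean_deviance": mean_dev, "se_deviance": se_dev}
        )
        return PenalizedCoxResults(
            self, full_coefs[:, j_sel], float(lambdas[j_sel]), lambda_rule, cv_path
        )


@dataclass
class PenalizedCoxResults:
    """Fitted penalized Cox model: coefficients and the CV path."""

    model: PenalizedCox
    beta: np.ndarray
    lambda_: float
    lambda_rule: str
    cv_path: pd.DataFrame | None = None

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.model.X.columns, name="beta")

    @property
    def nonzero_features(self) -> list[str]:
        return [str(c) for c, b in self.params.items() if b != 0]

    def predict(self, X) -> np.ndarray:
        """Prognosis index (log hazard ratio) X @ beta."""
        Xf = _as_frame(X)
        if list(Xf.columns) != list(self.model.X.columns) and Xf.shape[1] != len(self.beta):
            raise ValueError("feature dimension mismatch")
        return Xf.to_numpy() @ self.beta

    def evaluate(self, X, surv: SurvivalData, method: str = "median") -> PrognosisEvaluation:
        return _evaluate_pi(self.predict(X), surv, method)

    def summary(self) -> pd.DataFrame:
        out = self.params.to_frame()
        out["selected"] = out["beta"] != 0
        out.attrs["lambda"] = self.lambda_
        out.attrs["lambda_rule"] = self.lambda_rule
        out.attrs["alpha"] = self.model.alpha
        return out


# --------------------------------------------------------------------------
# Cox neural network


@dataclass
class CoxnnetConfig:
    """Optimizer settings for the Cox neural network."""

    algorithm: str = "standard"          # standard | momentum | nesterov
    learning_rate: float = 0.01
    momentum_frac: float = 0.9
    lr_increase: float = 1.1
    lr_decrease: float = 0.5
    eval_interval: int = 10
    max_iter: int = 2000
    stop_threshold: float = 1e-5
    min_iter: int = 100
    patience: int = 500
    seed: int = 0


_ACTIVATIONS = {
    "tanh": (np.tanh, lambda pre, h: 1.0 - h * h),
    "rectifier": (lambda z: np.maximum(z, 0.0), lambda pre, h: (pre > 0).astype(float)),
    "identity": (lambda z: z, lambda pre, h: np.ones_like(pre)),
}


class CoxNeuralNet:
    """One-hidden-layer Cox regression network.

    theta_i = G(W x_i + b)' beta, trained by minimizing
    Cost = -pl(beta, W) + lambda (||beta||^2 + ||W||^2) with plain,
    momentum or Nesterov gradient descent and a multiplicative
    learning-rate adaptation.
    """

    def __init__(
        self,
        X,
        surv: SurvivalData,
        hidden_size: int | None = None,
        activation: str = "tanh",
        lambda_: float = 0.0,
    ):
        self.X = _as_frame(X)
        if len(self.X) != len(surv):
            raise ValueError("X and survival data are not aligned")
        self.surv = surv
        p = self.X.shape[1]
        self.hidden_size = int(hidden_size) if hidden_size else int(np.ceil(np.sqrt(p)))
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.lambda_ = float(lambda_)

    # -- cost and gradient -------------------------------------------------

    def _unpack(self, flat: np.ndarray):
        p, h = self.X.shape[1], self.hidden_size
        W = flat[: h * p].reshape(h, p)
        b = flat[h * p : h * p + h]
        beta = flat[h * p + h :]
        return W, b, beta

    def cost_grad(self, flat: np.ndarray, Xnp=None, surv=None):
        """Cost and its gradient wrt the flattened (W, b, beta)."""
        Xnp = self.X.to_numpy() if Xnp is None else Xnp
        surv = self.surv if surv is None else surv
        W, b, beta = self._unpack(flat)
        G, Gprime = _ACTIVATIONS[self.activation]
        pre = Xnp @ W.T + b
        H = G(pre)
        theta = H @ beta
        pl = cox_partial_loglik(theta, surv)
        g = cox_partial_loglik_grad(theta, surv)
        cost = -pl + self.lambda_ * (beta @ beta + np.sum(W * W))
        dbeta = -(H.T @ g) + 2 * self.lambda_ * beta
        dH = -np.outer(g, beta)
        dpre = dH * Gprime(pre, H)
        dW = dpre.T @ Xnp + 2 * self.lambda_ * W
        db = dpre.sum(axis=0)
        return cost, np.concatenate([dW.ravel(), db, dbeta])

    # -- training ----------------------------------------------------------

    def fit(self, config: CoxnnetConfig | None = None) -> "CoxNeuralNetResults":
        cfg = config or CoxnnetConfig()
        if cfg.algorithm not in {"standard", "momentum", "nesterov"}:
            raise ValueError(f"unknown gradient descent algorithm {cfg.algorithm!r}")
        rng = np.random.default_rng(cfg.seed)
        p, h = self.X.shape[1], self.hidden_size
        W = rng.normal(0.0, 1.0 / np.sqrt(p), size=(h, p))
        b = np.zeros(h)
        beta = rng.normal(0.0, 0.01, size=h)
        flat = np.concatenate([W.ravel(), b, beta])
        velocity = np.zeros_like(flat)
        lr = cfg.learning_rate

        # gradient scaled by the event count so the step size is
        # insensitive to cohort size
        scale = 1.0 / max(1, self.surv.n_events)
        cost, grad = self.cost_grad(flat)
        best_cost, best_flat, best_iter = cost, flat.copy(), 0
        checkpoint_cost = cost
        history = [cost]
        for it in range(1, cfg.max_iter + 1):
            prev_flat, prev_vel = flat, velocity
            if cfg.algorithm == "nesterov":
                _, grad = self.cost_grad(flat + cfg.momentum_frac * velocity)
                velocity = cfg.momentum_frac * velocity - lr * scale * grad
                flat = flat + velocity
            elif cfg.algorithm == "momentum":
                velocity = cfg.momentum_frac * velocity - lr * scale * grad
                flat = flat + velocity
            else:
                flat = flat - lr * scale * grad
            cost, grad = self.cost_grad(flat)
            diverged = (not np.isfinite(cost)) or cost > 10.0 * abs(history[-1]) + 10.0
            if diverged:
                # runaway step: revert and shrink the learning rate
                lr *= cfg.lr_decrease
                if lr < 1e-12:
                    raise FloatingPointError(f"non-finite cost at iteration {it}")
                flat, velocity = prev_flat, prev_vel
                cost, grad = self.cost_grad(flat)
                continue
            history.append(cost)
            if cost < best_cost:
                best_cost, best_flat, best_iter = cost, flat.copy(), it
            if it % cfg.eval_interval == 0:
                if cost < checkpoint_cost:
                    lr *= cfg.lr_increase
                else:
                    lr *= cfg.lr_decrease
                improvement = (checkpoint_cost - cost) / max(abs(checkpoint_cost), 1e-12)
                checkpoint_cost = cost
                if it >= cfg.min_iter and improvement < cfg.stop_threshold:
                    break
            if it - best_iter > cfg.patience:
                break
        W, b, beta = self._unpack(best_flat)
        return CoxNeuralNetResults(self, W, b, beta, cfg, history, it)

    def select_lambda(
        self, lambdas, cv_folds: int = 5, seed: int = 0, config: CoxnnetConfig | None = None
    ) -> float:
        """Pick lambda maximizing the mean CV partial likelihood."""
        folds = _cv_fold_indices(len(self.surv), cv_folds, self.surv.event, seed)
        Xnp = self.X.to_numpy()
        means = []
        for lam in lambdas:
            vals = []
            for test_idx in folds:
                train_idx = np.setdiff1d(np.arange(len(self.surv)), test_idx)
                sub = CoxNeuralNet(
                    self.X.iloc[train_idx],
                    self.surv.subset(train_idx),
                    hidden_size=self.hidden_size,
                    activation=self.activation,
                    lambda_=lam,
                )
                res = sub.fit(config)
                theta = res.predict(Xnp)
                vals.append(_cv_pl(theta, self.surv, train_idx))
            means.append(float(np.mean(vals)))
        return float(np.asarray(lambdas)[int(np.argmax(means))])


@dataclass
class CoxNeuralNetResults:
    """Fitted Cox network: weights, training history, prediction."""

    model: CoxNeuralNet
    W: np.ndarray
    b: np.ndarray
    beta: np.ndarray
    config: CoxnnetConfig
    cost_history: list[float] = field(repr=False, default_factory=list)
    n_iter: int = 0

    def predict(self, X) -> np.ndarray:
        """Prognosis index G(W x + b)' beta per row of X."""
        Xnp = _as_frame(X).to_numpy() if not isinstance(X, np.ndarray) else X
        if Xnp.shape[1] != self.W.shape[1]:
            raise ValueError("feature dimension mismatch")
        G, _ = _ACTIVATIONS[self.model.activation]
        return G(Xnp @ self.W.T + self.b) @ self.beta

    def evaluate(self, X, surv: SurvivalData, method: str = "median") -> PrognosisEvaluation:
        return _evaluate_pi(self.predict(X), surv, method)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": ["hidden_size", "activation", "lambda", "final_cost", "n_iter"],
                "value": [
                    self.model.hidden_size,
                    self.model.activation,
                    self.model.lambda_,
                    self.cost_history[-1] if self.cost_history else np.nan,
                    self.n_iter,
                ],
            }
        )


# --------------------------------------------------------------------------
# functional conveniences


def fit_penalized_cox(
    X,
    surv: SurvivalData,
    alpha: float = 1.0,
    lambda_rule: str = "lambda_1se",
    cv_folds: int = 5,
    seed: int = 0,
    lambda_: float | None = None,
) -> PenalizedCoxResults:
    """Fit an elastic-net Cox model (see :class:`PenalizedCox`)."""
    return PenalizedCox(X, surv, alpha=alpha).fit(
        lambda_rule=lambda_rule, cv_folds=cv_folds, seed=seed, lambda_=lambda_
    )


def fit_coxnnet(
    X,
    surv: SurvivalData,
    hidden_size: int | None = None,
    activation: str = "tanh",
    lambda_: float = 0.0,
    config: CoxnnetConfig | None = None,
) -> CoxNeuralNetResults:
    """Fit a Cox neural network (see :class:`CoxNeuralNet`)."""
    return CoxNeuralNet(
        X, surv, hidden_size=hidden_size, activation=activation, lambda_=lambda_
    ).fit(config)


def prognosis_index(results, X) -> np.ndarray:
    """Per-sample prognosis index (log hazard ratio) of a fitted model."""
    return results.predict(X)


def evaluate_prognosis(
    results,
    X,
    surv: SurvivalData,
    method: str = "median",
    cv_folds: int | None = None,
    seed: int = 0,
) -> PrognosisEvaluation:
    """Evaluate a fitted prognosis model: C-index, log-rank, KM tables.

    With ``cv_folds`` set, the model is refitted on each training fold
    and the pooled out-of-fold PI (one entry per sample) is evaluated
    instead of the in-sample PI.
    """
    if cv_folds is None:
        return _evaluate_pi(results.predict(X), surv, method)
    model = results.model
    Xf = _as_frame(X)
    folds = _cv_fold_indices(len(surv), cv_folds, surv.event, seed)
    pi = np.empty(len(surv))
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(surv)), test_idx)
        str_ = surv.subset(train_idx)
        if isinstance(model, PenalizedCox):
            sub = PenalizedCox(Xf.iloc[train_idx], str_, alpha=model.alpha)
            res = sub.fit(
                lambda_rule=results.lambda_rule if results.lambda_rule != "fixed" else "lambda_1se",
                seed=seed,
                lambda_=results.lambda_ if results.lambda_rule == "fixed" else None,
            )
        else:
            sub = CoxNeuralNet(
                Xf.iloc[train_idx],
                str_,
                hidden_size=model.hidden_size,
                activation=model.activation,
                lambda_=model.lambda_,
            )
            res = sub.fit(results.config)
        pi[test_idx] = res.predict(Xf.iloc[test_idx])
    return _evaluate_pi(pi, surv, method)
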