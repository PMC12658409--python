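"""Regression layer: chance-level logistic tests, deviation-coded
random-intercept logistic mixed models with likelihood-ratio comparison,
and OLS for slider ratings.

The mixed model is a binomial GLMM with a single Gaussian random intercept
per participant, fit by maximizing the marginal likelihood with adaptive
Gauss-Hermite quadrature. The learning design has only between-participant
fixed effects, so a per-participant random slope is not identifiable and
the random effect is an intercept. Plain logistic and OLS fits delegate to
statsmodels; the intercept-only chance test has the usual closed form
(beta = logit(k/n), Wald SE = 1/sqrt(n p (1-p))).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit, log_expit, logit, logsumexp

__all__ = [
    "ModelFit",
    "CodedFactor",
    "SeparationError",
    "RandomInterceptLogit",
    "fit_logistic_intercept",
    "fit_logistic",
    "fit_logit_glmm",
    "likelihood_ratio_test",
    "fit_ols_rating",
    "MAJORITY_NATURAL_CODES",
    "MEANING_TYPE_CODES",
]


class SeparationError(ValueError):
    """Raised when a logistic estimate is infinite (all 0s or all 1s)."""


@dataclass(frozen=True)
class ModelFit:
    """Fitted-model summary: named coefficients with Wald statistics.

    ``deviance`` is -2 log-likelihood (for the GLMM, of the marginal
    likelihood), so nested fits can be compared by likelihood-ratio test.
    ``extra`` carries model-specific quantities such as the random-effect
    SD.
    """

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    statistic: np.ndarray
    p_values: np.ndarray
    deviance: float
    n_obs: int
    converged: bool
    stat_label: str = "z"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.names)
        if not (len(self.coef) == len(self.se) == len(self.statistic) == len(self.p_values) == k):
            raise ValueError("coefficient vectors have inconsistent lengths")

    @property
    def n_params(self) -> int:
        return len(self.names) + int("random_effect_sd" in self.extra)

    def __getitem__(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "coef": float(self.coef[i]),
            "se": float(self.se[i]),
            self.stat_label: float(self.statistic[i]),
            "p": float(self.p_values[i]),
        }

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                self.stat_label: self.statistic,
                "p": self.p_values,
            },
            index=list(self.names),
        )

    def to_dict(self) -> dict:
        d = {
            "terms": {n: self[n] for n in self.names},
            "deviance": self.deviance,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }
        d.update({k: v for k, v in self.extra.items()})
        return d


@dataclass(frozen=True)
class CodedFactor:
    """Deviation coding of a two-level factor as +/-0.5.

    Coefficients of deviation-coded predictors are differences from the
    grand mean rather than from a reference level.
    """

    name: str
    codes: dict

    def __post_init__(self) -> None:
        vals = sorted(self.codes.values())
        if vals != [-0.5, 0.5]:
            raise ValueError("deviation codes must be exactly {-0.5, +0.5}")

    def code(self, values) -> np.ndarray:
        try:
            return np.array([self.codes[v] for v in values], dtype=float)
        except KeyError as e:
            raise ValueError(f"unknown level {e.args[0]!r} for factor {self.name}") from None

    def flipped(self) -> "CodedFactor":
        return CodedFactor(self.name, {k: -v for k, v in self.codes.items()})


#: Published codings: possessive = +0.5, descriptive = -0.5; natural = +0.5.
MEANING_TYPE_CODES = CodedFactor("meaning_type", {"possessive": 0.5, "descriptive": -0.5})
MAJORITY_NATURAL_CODES = CodedFactor("majority_natural", {True: 0.5, False: -0.5})


def _wald_p(z: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


def fit_logistic_intercept(k: int, n: int) -> ModelFit:
    """Closed-form intercept-only logistic chance test on k successes of n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("require 0 <= k <= n, n > 0")
    if k == 0 or k == n:
        raise SeparationError("all responses identical: intercept estimate is infinite")
    p_hat = k / n
    beta = float(logit(p_hat))
    se = 1.0 / np.sqrt(n * p_hat * (1.0 - p_hat))
    z = beta / se
    ll = k * np.log(p_hat) + (n - k) * np.log(1 - p_hat)
    return ModelFit(
        names=("intercept",),
        coef=np.array([beta]),
        se=np.array([se]),
        statistic=np.array([z]),
        p_values=_wald_p(np.array([z])),
        deviance=float(-2 * ll),
        n_obs=n,
        converged=True,
    )


def fit_logistic(outcome, predictors=None, names: tuple[str, ...] | None = None) -> ModelFit:
    """Maximum-likelihood logistic regression (statsmodels GLM/IRLS).

    ``predictors`` is an (n, k) array of columns appended to an intercept;
    None fits intercept-only.
    """
    y = np.asarray(outcome, dtype=float)
    if predictors is None:
        X = np.ones((y.size, 1))
        names = names or ("intercept",)
    else:
        P = np.atleast_2d(np.asarray(predictors, dtype=float))
        if P.shape[0] != y.size:
            P = P.T
        X = np.column_stack([np.ones(y.size), P])
        names = names or ("intercept",) + tuple(f"x{i + 1}" for i in range(P.shape[1]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    z = res.params / res.bse
    converged = bool(res.converged) and bool(np.all(np.abs(res.params) < 15))
    return ModelFit(
        names=tuple(names),
        coef=np.asarray(res.params),
        se=np.asarray(res.bse),
        statistic=np.asarray(z),
        p_values=_wald_p(np.asarray(z)),
        deviance=float(-2 * res.llf),
        n_obs=int(y.size),
        converged=converged,
    )


class RandomInterceptLogit:
    """Logistic mixed model with one Gaussian random intercept per group.

    Parameters
    ----------
    quad_nodes : int
        Number of adaptive Gauss-Hermite quadrature nodes per group
        (1 = Laplace approximation).
    tol : float
        Gradient-norm convergence tolerance of the outer optimizer.
    max_iter : int
        Maximum outer iterations.

    Attributes (after fit)
    ----------------------
    coef_ : fixed-effect estimates (intercept first)
    se_ : Wald standard errors from the numerical Hessian
    random_effect_sd_ : estimated SD of the random intercept
    deviance_ : -2 marginal log-likelihood
    converged_ : optimizer success flag
    """

    def __init__(self, quad_nodes: int = 10, tol: float = 1e-8, max_iter: int = 200):
        self.quad_nodes = quad_nodes
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"quad_nodes": self.quad_nodes, "tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params) -> "RandomInterceptLogit":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # --- marginal log-likelihood by adaptive Gauss-Hermite quadrature ---

    def _neg_loglik(self, theta: np.ndarray) -> float:
        beta, sigma = theta[:-1], abs(theta[-1])
        a = self._X @ beta
        gi, y = self._gi, self._y
        G = self._n_groups
        # inner Newton: per-group mode of log p(y_i|v) + log phi(v), v ~ N(0,1)
        v = np.zeros(G)
        for _ in range(50):
            mu = expit(a + sigma * v[gi])
            g1 = sigma * np.bincount(gi, y - mu, minlength=G) - v
            g2 = -(sigma**2) * np.bincount(gi, mu * (1 - mu), minlength=G) - 1.0
            step = g1 / g2
            v_new = v - step
            if np.max(np.abs(step)) < 1e-10:
                v = v_new
                break
            v = v_new
        curv = (sigma**2) * np.bincount(gi, mu * (1 - mu), minlength=G) + 1.0
        scale = np.sqrt(2.0 / curv)
        nodes, weights = np.polynomial.hermite.hermgauss(self.quad_nodes)
        # log integrand at shifted/scaled nodes, per group x node
        contrib = np.empty((G, self.quad_nodes))
        for q, (xq, wq) in enumerate(zip(nodes, weights)):
            vq = v + scale * xq
            eta = a + sigma * vq[gi]
            ll_bin = np.bincount(
                gi, y * log_expit(eta) + (1 - y) * log_expit(-eta), minlength=G
            )
            log_phi = -0.5 * vq**2 - 0.5 * np.log(2 * np.pi)
            contrib[:, q] = np.log(wq) + xq**2 + ll_bin + log_phi
        group_ll = np.log(scale) + logsumexp(contrib, axis=1)
        return -float(group_ll.sum())

    def fit(self, X, y, groups) -> "RandomInterceptLogit":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        groups = np.asarray(groups)
        if not (len(X) == len(y) == len(groups)):
            raise ValueError("X, y, groups must have equal length")
        _, gi = np.unique(groups, return_inverse=True)
        if gi.max() + 1 < 2:
            raise ValueError("need at least 2 groups")
        self._X, self._y, self._gi = X, y, gi
        self._n_groups = int(gi.max() + 1)
        p = X.shape[1]
        # warm start at the pooled logistic estimate, sigma = 0.5
        try:
            beta0 = sm.GLM(y, X, family=sm.families.Binomial()).fit().params
        except Exception:
            beta0 = np.zeros(p)
        theta0 = np.append(beta0, 0.5)
        res = optimize.minimize(
            self._neg_loglik,
            theta0,
            method="L-BFGS-B",
            bounds=[(None, None)] * p + [(0.0, None)],
            options={"maxiter": self.max_iter, "gtol": self.tol, "ftol": 1e-12},
        )
        theta = res.x
        self.coef_ = theta[:-1].copy()
        self.random_effect_sd_ = float(abs(theta[-1]))
        self.deviance_ = float(2.0 * res.fun)
        self.converged_ = bool(res.success)
        self.n_obs_ = int(len(y))
        self.n_groups_ = self._n_groups
        se_all = self._wald_se(theta)
        self.se_ = se_all[:-1]
        self.random_effect_sd_se_ = float(se_all[-1])
        del self._X, self._y, self._gi
        return self

    def _wald_se(self, theta: np.ndarray) -> np.ndarray:
        """SEs from a central-difference Hessian of the negative log-lik."""
        k = theta.size
        h = np.maximum(1e-4, 1e-4 * np.abs(theta))
        if theta[-1] < 2 * h[-1]:  # sigma near the boundary: one-sided info
            h[-1] = max(theta[-1] / 2, 1e-6)
        H = np.empty((k, k))
        f = self._neg_loglik
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                fpp = f(theta + ei + ej)
                fpm = f(theta + ei - ej)
                fmp = f(theta - ei + ej)
                fmm = f(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov).copy()
            d[d < 0] = np.nan
            return np.sqrt(d)
        except np.linalg.LinAlgError:
            return np.full(k, np.nan)

    def predict_proba(self, X) -> np.ndarray:
        """Marginal (random effect at 0) success probabilities."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return expit(X @ self.coef_)

    def to_model_fit(self, names: tuple[str, ...]) -> ModelFit:
        z = self.coef_ / self.se_
        return ModelFit(
            names=tuple(names),
            coef=self.coef_,
            se=self.se_,
            statistic=z,
            p_values=_wald_p(z),
            deviance=self.deviance_,
            n_obs=self.n_obs_,
            converged=self.converged_,
            extra={
                "random_effect_sd": self.random_effect_sd_,
                "random_effect_sd_se": self.random_effect_sd_se_,
                "n_groups": self.n_groups_,
            },
        )


def _glmm_design(
    trials: pd.DataFrame, outcome: str, fixed: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    test = trials[trials["phase"] == "test"]
    if test.empty:
        raise ValueError("no test-phase rows in trial table")
    col = {"majority_order": "is_majority", "natural_order": "is_natural"}[outcome]
    y = test[col].astype(float).to_numpy()
    groups = test["participant_id"].to_numpy()
    nat = MAJORITY_NATURAL_CODES.code(
        [_condition_is_natural(lbl) for lbl in test["condition"]]
    )
    mean = MEANING_TYPE_CODES.code(test["meaning_type"])
    cols, names = [np.ones(len(test))], ["intercept"]
    if "majority_natural" in fixed:
        cols.append(nat)
        names.append("majority_natural")
    if "meaning_type" in fixed:
        cols.append(mean)
        names.append("meaning_type")
    if "interaction" in fixed:
        cols.append(nat * mean)
        names.append("majority_natural:meaning_type")
    return np.column_stack(cols), y, groups, tuple(names)


def _condition_is_natural(label: str) -> bool:
    return label.strip().lower().startswith("natural")


def fit_logit_glmm(
    trials: pd.DataFrame,
    outcome: str = "majority_order",
    fixed: tuple[str, ...] = (),
    quad_nodes: int = 10,
) -> ModelFit:
    """Random-intercept logistic mixed model on test-phase choices.

    ``outcome`` is 'majority_order' (did the choice match the training
    majority) or 'natural_order'; ``fixed`` selects deviation-coded terms
    from {'majority_natural', 'meaning_type', 'interaction'} beyond the
    intercept.
    """
    X, y, groups, names = _glmm_design(trials, outcome, tuple(fixed))
    est = RandomInterceptLogit(quad_nodes=quad_nodes).fit(X, y, groups)
    return est.to_model_fit(names)


def likelihood_ratio_test(null_fit: ModelFit, full_fit: ModelFit) -> tuple[float, int, float]:
    """Compare nested fits: chi2 = deviance(null) - deviance(full)."""
    if null_fit.n_obs != full_fit.n_obs:
        raise ValueError("fits are on different data (n_obs differs)")
    df = full_fit.n_params - null_fit.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters than null model")
    chi2 = max(null_fit.deviance - full_fit.deviance, 0.0)
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p


def fit_ols_rating(
    ratings,
    predicted_order,
    condition_codes=None,
    interaction: bool = False,
) -> ModelFit:
    """OLS on transformed slider ratings.

    Predictors: predicted_order (binary), optionally a coded condition term
    and its interaction with predicted_order.
    """
    y = np.asarray(ratings, dtype=float)
    po = np.asarray(predicted_order, dtype=float)
    cols, names = [np.ones(y.size), po], ["intercept", "predicted_order"]
    if condition_codes is not None:
        cc = np.asarray(condition_codes, dtype=float)
        cols.append(cc)
        names.append("condition")
        if interaction:
            cols.append(po * cc)
            names.append("predicted_order:condition")
    elif interaction:
        raise ValueError("interaction requires condition_codes")
    X = np.column_stack(cols)
    if y.size < X.shape[1] + 1:
        raise ValueError("too few observations")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("collinear design")
    res = sm.OLS(y, X).fit()
    t = res.params / res.bse
    return ModelFit(
        names=tuple(names),
        coef=np.asarray(res.params),
        se=np.asarray(res.bse),
        statistic=np.asarray(t),
        p_values=np.asarray(res.pvalues),
        deviance=float(-2 * res.llf),
        n_obs=int(y.size),
        converged=True,
        stat_label="t",
    )
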