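"""Random-intercept logistic regression by maximum likelihood.

The model for embryo j of carrier i is

    logit P(y_ij = 1 | u_i) = x_ij' beta + u_i,   u_i ~ N(0, sigma^2),

the standard clustered-binary GLMM with one random intercept per carrier.
The marginal log-likelihood integrates u_i out with Gauss-Hermite
quadrature (non-adaptive, 25 nodes by default — ample for the moderate
sigma and small cluster sizes this package deals with) and is maximised
with BFGS on (beta, log sigma). Wald standard errors come from the inverse
numerical Hessian at the optimum.

statsmodels offers no frequentist binomial GLMM (MixedLM is linear-only),
so the fit is implemented here; tests cross-check it against lme4's
``glmer`` and against plain logistic regression in the sigma -> 0 limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

_DEFAULT_NODES = 25
_LOG_SIGMA_FLOOR = -8.0  # sigma ~ 3e-4: numerically the no-random-effect model
_LOG_SIGMA_CEIL = 3.0  # sigma ~ 20 log-odds: far beyond any plausible frailty


class GLMMError(RuntimeError):
    """Degenerate design or failed fit."""


@dataclass
class GLMMFit:
    """Result of a random-intercept logistic fit.

    ``coefficients`` is indexed by term with columns coef / se / or /
    ci_low / ci_high / p (OR scale for the last four except p).
    """

    outcome: str
    terms: list[str]
    coefficients: pd.DataFrame
    random_intercept_sd: float
    loglik: float
    loglik_null: float
    converged: bool
    n_obs: int
    n_groups: int
    n_iter: int
    message: str = ""
    extra: dict = field(default_factory=dict)

    def odds_ratio(self, term: str) -> float:
        return float(self.coefficients.loc[term, "or"])

    def p_value(self, term: str) -> float:
        return float(self.coefficients.loc[term, "p"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.coefficients.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def _group_index(groups: np.ndarray) -> tuple[np.ndarray, int]:
    _, idx = np.unique(groups, return_inverse=True)
    return idx, int(idx.max()) + 1


def _marginal_loglik(
    params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    gidx: np.ndarray,
    n_groups: int,
    nodes: np.ndarray,
    log_weights: np.ndarray,
) -> float:
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(min(max(log_sigma, _LOG_SIGMA_FLOOR), _LOG_SIGMA_CEIL))
    eta = X @ beta  # (n,)
    # (n, K): linear predictor shifted by each quadrature abscissa; clipped
    # so line-search probes at extreme sigma cannot overflow the exp
    shifted = np.clip(
        eta[:, None] + (np.sqrt(2.0) * sigma) * nodes[None, :], -500.0, 500.0
    )
    # log Bernoulli likelihood: y*eta_u - log(1 + exp(eta_u))
    ll_obs = np.where(y[:, None] == 1, shifted, 0.0) - np.logaddexp(0.0, shifted)
    # sum within cluster, then logsumexp over nodes with GH weights
    ll_grp = np.zeros((n_groups, nodes.size))
    np.add.at(ll_grp, gidx, ll_obs)
    return float(special.logsumexp(ll_grp + log_weights[None, :], axis=1).sum())


def fit_random_intercept_logit(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    terms: list[str],
    *,
    outcome: str = "event",
    n_quad: int = _DEFAULT_NODES,
    tol: float = 1e-8,
    maxiter: int = 200,
) -> GLMMFit:
    """Fit logit(P(y=1)) = X beta + u_group, u ~ N(0, sigma^2), by GH-ML.

    ``X`` must already contain an intercept column; ``terms`` names its
    columns. Deterministic (no stochastic initialisation): starting values
    are the plain-logistic estimates with a small sigma.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise GLMMError("X and y are not conformable")
    if y.size == 0:
        raise GLMMError("empty data")
    if not set(np.unique(y)) <= {0, 1}:
        raise GLMMError("outcome must be binary 0/1")
    for j, name in enumerate(terms):
        col = X[:, j]
        if not np.all(np.isfinite(col)):
            raise GLMMError(f"covariate {name!r} contains missing/non-finite values")
        if name != "intercept" and np.ptp(col) == 0:
            raise GLMMError(f"covariate {name!r} is constant across all rows")
    gidx, n_groups = _group_index(np.asarray(groups))
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)

    # deterministic start: plain logistic (a few Newton steps), sigma small
    beta0 = _logistic_start(X, y)
    x0 = np.append(beta0, np.log(0.3))

    def nll(p: np.ndarray) -> float:
        p = p.copy()
        p[-1] = min(max(p[-1], _LOG_SIGMA_FLOOR), _LOG_SIGMA_CEIL)
        return -_marginal_loglik(p, X, y, gidx, n_groups, nodes, log_w)

    res = optimize.minimize(
        nll, x0, method="BFGS",
        options={"gtol": 1e-6, "maxiter": maxiter},
    )
    params = res.x.copy()
    params[-1] = min(max(params[-1], _LOG_SIGMA_FLOOR), _LOG_SIGMA_CEIL)
    loglik = -nll(params)
    # gradient-based convergence check; BFGS "precision loss" at a genuine
    # optimum still counts as converged when the gradient is flat relative
    # to the log-likelihood scale
    grad_ok = float(np.max(np.abs(res.jac))) < 1e-4 * max(1.0, abs(loglik))
    converged = bool(res.success) or grad_ok

    # null (intercept-only) fit for the nesting diagnostic
    Xn = X[:, :1]
    resn = optimize.minimize(
        lambda p: -_marginal_loglik(p, Xn, y, gidx, n_groups, nodes, log_w),
        np.array([special.logit(max(min(y.mean(), 1 - 1e-9), 1e-9)), np.log(0.3)]),
        method="BFGS", options={"gtol": 1e-6, "maxiter": maxiter},
    )
    loglik_null = -resn.fun

    hess = numdiff.approx_hess1(params, nll)
    se = None
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)[:-1]
        if np.all(diag > 0):
            se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        pass
    if se is None:
        # sigma at/near the boundary leaves the log-sigma direction flat and
        # the full Hessian ill-conditioned; condition on sigma-hat and use
        # the beta block (the cross-terms vanish there)
        try:
            se = np.sqrt(np.clip(np.diag(np.linalg.inv(hess[:-1, :-1])), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(len(terms), np.nan)
            converged = False

    beta = params[:-1]
    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    coef = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "or": np.exp(beta),
            "ci_low": np.exp(beta - 1.959964 * se),
            "ci_high": np.exp(beta + 1.959964 * se),
            "p": pvals,
        },
        index=pd.Index(terms, name="term"),
    )
    fit = GLMMFit(
        outcome=outcome,
        terms=list(terms),
        coefficients=coef,
        random_intercept_sd=float(np.exp(params[-1])),
        loglik=loglik,
        loglik_null=float(loglik_null),
        converged=converged,
        n_obs=int(y.size),
        n_groups=n_groups,
        n_iter=int(res.nit),
        message=str(res.message),
    )
    if not converged:
        fit.message = f"non-convergence: {res.message} (|grad|max={np.max(np.abs(res.jac)):.2e})"
    return fit


def _logistic_start(X: np.ndarray, y: np.ndarray, n_steps: int = 25) -> np.ndarray:
    """Newton-IRLS plain-logistic estimate used as a deterministic start."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_steps):
        eta = X @ beta
        mu = special.expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X + 1e-8 * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta
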