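"""Cumulative-logit (proportional-odds) fitting and the score test for
slope heterogeneity.

The proportional-odds model for an ordinal outcome Y in {1, ..., 4} is

    logit P(Y <= k | x) = alpha_k + x' gamma,   k = 1, 2, 3

with one shared slope vector gamma across the three cutpoints. The
unconstrained alternative gives each cutpoint its own slope vector gamma_k.
:func:`po_score_test` fits the constrained model by maximum likelihood and
evaluates the Rao score statistic of the unconstrained model there:

    S = U' I^{-1} U,    df = (K - 2) * p = 2 * 5 = 10

where U is the unconstrained score and I the observed information (both at
the constrained MLE). A baseline-category logit data-generating process with
markedly different slopes per category — as fitted transition models for BMI
categories typically are — violates proportionality strongly, so the test
serves as a formal check that the extra flexibility of the
baseline-category model is needed.

Predictors are standardised internally (the statistic is invariant under
nonsingular linear reparametrisation); cutpoints are kept ordered via a
log-increment parametrisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2

from .model import design_matrix, _observed_outcomes

N_CUTPOINTS = 3


@dataclass
class ScoreTestResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class POFit:
    """Constrained (shared-slope) cumulative-logit fit on standardised X."""

    alphas: np.ndarray  # (3,) ordered cutpoints
    gamma: np.ndarray  # (p,) shared slopes (standardised predictor scale)
    loglik: float
    converged: bool
    n_iter: int


def _cumprobs(alphas, gamma_stack, X):
    """F (n x 3) cumulative probabilities; gamma_stack is (3, p)."""
    eta = alphas[None, :] + X @ gamma_stack.T
    return expit(eta)


def _cell_probs(F, y):
    """P(Y = y_i) from cumulative probabilities."""
    Fpad = np.column_stack([np.zeros(len(F)), F, np.ones(len(F))])
    return Fpad[np.arange(len(F)), y] - Fpad[np.arange(len(F)), y - 1]


def _eta_scores(F, y, p_cell):
    """s (n x 3): d(-loglik)/d(eta_k) per observation."""
    f = F * (1.0 - F)
    n = len(F)
    s = np.zeros((n, N_CUTPOINTS))
    rows = np.arange(n)
    for k in range(1, N_CUTPOINTS + 1):
        contrib = np.zeros(n)
        contrib[y == k] = 1.0
        contrib[y == k + 1] = -1.0
        s[:, k - 1] = -f[:, k - 1] * contrib / p_cell
    _ = rows
    return s


def _po_nll_grad(theta, X, y):
    """Negative log-likelihood and gradient in the (a1, log d2, log d3, gamma)
    parametrisation of the shared-slope model."""
    p = X.shape[1]
    t1, t2, t3 = theta[0], theta[1], theta[2]
    alphas = np.array([t1, t1 + np.exp(t2), t1 + np.exp(t2) + np.exp(t3)])
    gamma = theta[3:]
    F = _cumprobs(alphas, np.tile(gamma, (N_CUTPOINTS, 1)), X)
    p_cell = _cell_probs(F, y)
    if np.any(p_cell <= 0):
        return np.inf, np.zeros_like(theta)
    nll = -float(np.log(p_cell).sum())
    s = _eta_scores(F, y, p_cell)  # n x 3
    g_alpha = s.sum(axis=0)  # d nll / d alpha_k
    g_gamma = X.T @ s.sum(axis=1)
    grad = np.empty(3 + p)
    grad[0] = g_alpha.sum()
    grad[1] = (g_alpha[1] + g_alpha[2]) * np.exp(t2)
    grad[2] = g_alpha[2] * np.exp(t3)
    grad[3:] = g_gamma
    return nll, grad


def fit_proportional_odds(X, y, tol: float = 1e-10, max_iter: int = 500) -> POFit:
    """Maximum-likelihood fit of the shared-slope cumulative-logit model.

    ``X`` (n x p, no intercept) should be on a reasonable scale; ``y`` takes
    values in {1, ..., 4} with at least three categories present.
    """
    y = np.asarray(y, dtype=int)
    present = np.unique(y)
    if len(present) < 3:
        raise ValueError("need at least 3 outcome categories for an ordinal fit")
    shares = np.array([(y <= k).mean() for k in range(1, N_CUTPOINTS + 1)])
    shares = np.clip(shares, 1e-4, 1 - 1e-4)
    # enforce strictly increasing empirical cumulative shares for the start
    shares = np.maximum.accumulate(shares + 1e-9 * np.arange(N_CUTPOINTS))
    a0 = np.log(shares / (1 - shares))
    d = np.diff(a0)
    d = np.maximum(d, 1e-6)
    theta0 = np.concatenate([[a0[0]], np.log(d), np.zeros(X.shape[1])])
    res = minimize(
        _po_nll_grad,
        theta0,
        args=(X, y),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
    )
    t1, t2, t3 = res.x[0], res.x[1], res.x[2]
    alphas = np.array([t1, t1 + np.exp(t2), t1 + np.exp(t2) + np.exp(t3)])
    return POFit(
        alphas=alphas,
        gamma=res.x[3:],
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
    )


def _unconstrained_grad(theta_u, X, y):
    """Score (gradient of the log-likelihood) of the non-parallel cumulative
    model at theta_u = (alpha_1..3, gamma_1 (p), gamma_2 (p), gamma_3 (p))."""
    p = X.shape[1]
    alphas = theta_u[:N_CUTPOINTS]
    gammas = theta_u[N_CUTPOINTS:].reshape(N_CUTPOINTS, p)
    F = _cumprobs(alphas, gammas, X)
    p_cell = _cell_probs(F, y)
    if np.any(p_cell <= 0):
        raise FloatingPointError("non-positive cell probability in score evaluation")
    s = _eta_scores(F, y, p_cell)  # n x 3, d(-ll)/d eta_k
    grad = np.empty(N_CUTPOINTS + N_CUTPOINTS * p)
    grad[:N_CUTPOINTS] = -s.sum(axis=0)
    for k in range(N_CUTPOINTS):
        grad[N_CUTPOINTS + k * p:N_CUTPOINTS + (k + 1) * p] = -(X.T @ s[:, k])
    return grad


def _observed_information(theta_u, X, y, h: float = 1e-5):
    """Observed information of the unconstrained model by central differences
    of the analytic score."""
    m = len(theta_u)
    info = np.empty((m, m))
    for i in range(m):
        step = h * max(1.0, abs(theta_u[i]))
        plus = theta_u.copy()
        minus = theta_u.copy()
        plus[i] += step
        minus[i] -= step
        info[i] = -(_unconstrained_grad(plus, X, y) - _unconstrained_grad(minus, X, y)) / (2 * step)
    return 0.5 * (info + info.T)


def score_test_from_arrays(X, y, tol: float = 1e-10, max_iter: int = 500) -> ScoreTestResult:
    """Proportional-odds score test on a raw design matrix (no intercept)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant predictor column; drop it before testing")
    Z = (X - mu) / sd
    fit = fit_proportional_odds(Z, y, tol=tol, max_iter=max_iter)
    if not fit.converged:
        raise RuntimeError("constrained proportional-odds fit did not converge")
    p = Z.shape[1]
    theta_u = np.concatenate([fit.alphas, np.tile(fit.gamma, N_CUTPOINTS)])
    U = _unconstrained_grad(theta_u, Z, y)
    info = _observed_information(theta_u, Z, y)
    stat = float(U @ np.linalg.solve(info, U))
    df = (N_CUTPOINTS - 1) * p
    return ScoreTestResult(statistic=max(stat, 0.0), df=df, p_value=float(chi2.sf(stat, df)))


def po_score_test(cohort, tol: float = 1e-10, max_iter: int = 500) -> ScoreTestResult:
    """Score test of proportional odds for the five-predictor transition model.

    Tests whether a single shared slope vector across the three category
    cutpoints suffices for ``category18`` given (gender, district, age,
    height, bmi13); df = 10 for this design.
    """
    X = design_matrix(cohort)[:, 1:]  # drop intercept; cutpoints play that role
    y = _observed_outcomes(cohort)
    return score_test_from_arrays(X, y, tol=tol, max_iter=max_iter)


def sample_po_categories(X, alphas, gamma, rng) -> np.ndarray:
    """Draw ordinal outcomes from a proportional-odds truth (for simulations)."""
    F = _cumprobs(np.asarray(alphas, dtype=float), np.tile(np.asarray(gamma, dtype=float), (N_CUTPOINTS, 1)), np.asarray(X, dtype=float))
    u = rng.random(len(F))
    return 1 + (u[:, None] > F).sum(axis=1)
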