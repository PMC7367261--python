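"""Baseline-category logit model of five-year BMI-category transitions.

The outcome is the follow-up nutrition category J in {1, 2, 3, 4} with
"normal" (J = 2) as the baseline. For predictors
x = (gender, district, age, height, bmi13) the model is

    log[ p_j(x) / p_2(x) ] = beta_{j,0} + sum_i beta_{j,i} x_i,   j in {1, 3, 4}

so that p_2(x) = 1 / (1 + sum_j exp(eta_j)) and p_j(x) = exp(eta_j) p_2(x).

Two estimators are provided:

* :func:`fit_smle` — separate maximum likelihood: one binary logistic
  regression of category j against the baseline on the subpopulation whose
  outcome lies in {j, 2}, for each j in {1, 3, 4}. The three fitted rows are
  assembled into one coefficient table. This is consistent for the
  multinomial parameters but does not maximise the joint likelihood.
* :func:`fit_gmle` — global maximum likelihood: Newton-Raphson on the full
  18-parameter multinomial likelihood, with step-halving.

Both return a :class:`FitResult`; by construction the full multinomial
log-likelihood at the GMLE is at least that at the SMLE whenever both
converge.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
import json

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

CATEGORIES = ("underweight", "overweight", "obese")  # model rows -> outcome codes 1, 3, 4
NONBASE_CODES = (1, 3, 4)
COLUMNS = ("intercept", "gender", "district", "age", "height", "bmi13")
N_PARAMS = len(CATEGORIES) * len(COLUMNS)  # 18


@dataclass
class ModelParams:
    """Coefficient table beta of shape (3, 6): rows underweight/overweight/
    obese (baseline "normal" fixed at zero), columns intercept + the five
    predictors in the order gender, district, age, height, bmi13."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if beta.shape != (len(CATEGORIES), len(COLUMNS)):
            raise ValueError(f"beta must have shape {(len(CATEGORIES), len(COLUMNS))}")
        if not np.all(np.isfinite(beta)):
            raise ValueError("beta entries must be finite")
        self.beta = beta

    @classmethod
    def zeros(cls) -> "ModelParams":
        return cls(np.zeros((len(CATEGORIES), len(COLUMNS))))

    @classmethod
    def from_flat(cls, flat) -> "ModelParams":
        return cls(np.asarray(flat, dtype=float).reshape(len(CATEGORIES), len(COLUMNS)))

    def flat(self) -> np.ndarray:
        return self.beta.ravel().copy()

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            payload = json.load(fh)
        if tuple(payload.get("categories", ())) != CATEGORIES:
            raise ValueError(f"params JSON categories must be {list(CATEGORIES)}")
        if tuple(payload.get("columns", ())) != COLUMNS:
            raise ValueError(f"params JSON columns must be {list(COLUMNS)}")
        return cls(np.asarray(payload["beta"], dtype=float))

    def to_json(self, path) -> None:
        payload = {
            "categories": list(CATEGORIES),
            "columns": list(COLUMNS),
            "beta": self.beta.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def _packaged(cls, name: str) -> "ModelParams":
        with resources.as_file(resources.files("bmitrans.data") / name) as path:
            return cls.from_json(path)

    @classmethod
    def reference_smle(cls) -> "ModelParams":
        """Separate-fit point estimates reported for the motivating 88,980-child
        cohort; the default generating truth of the synthetic cohort."""
        return cls._packaged("reference_params_smle.json")

    @classmethod
    def reference_gmle(cls) -> "ModelParams":
        """Joint-fit point estimates reported for the motivating cohort."""
        return cls._packaged("reference_params_gmle.json")


def design_matrix(cohort: pd.DataFrame) -> np.ndarray:
    """n x 6 design matrix (leading intercept column)."""
    X = np.column_stack(
        [
            np.ones(len(cohort)),
            cohort["gender"].to_numpy(dtype=float),
            cohort["district"].to_numpy(dtype=float),
            cohort["age"].to_numpy(dtype=float),
            cohort["height"].to_numpy(dtype=float),
            cohort["bmi13"].to_numpy(dtype=float),
        ]
    )
    return X


def _eta_matrix(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """n x 4 linear predictors in category order (1, 2, 3, 4); baseline = 0."""
    eta_nonbase = X @ beta.T  # n x 3, columns j = 1, 3, 4
    eta = np.zeros((X.shape[0], 4))
    eta[:, 0] = eta_nonbase[:, 0]
    eta[:, 2] = eta_nonbase[:, 1]
    eta[:, 3] = eta_nonbase[:, 2]
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor")
    return eta


def _probs_from_eta(eta: np.ndarray) -> np.ndarray:
    m = eta.max(axis=1, keepdims=True)
    e = np.exp(eta - m)
    return e / e.sum(axis=1, keepdims=True)


def probability_matrix(params: ModelParams, cohort: pd.DataFrame) -> np.ndarray:
    """n x 4 matrix of category probabilities, columns ordered (1, 2, 3, 4)."""
    return _probs_from_eta(_eta_matrix(params.beta, design_matrix(cohort)))


def category_probs(params: ModelParams, x) -> np.ndarray:
    """Four category probabilities at one predictor vector.

    ``x`` is ``(gender, district, age, height, bmi13)``; the intercept is
    implicit. Computed with max-subtraction so it is stable for linear
    predictors up to about +/-700. The result sums to 1 to 1e-12.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (5,):
        raise ValueError("x must be (gender, district, age, height, bmi13)")
    row = np.concatenate([[1.0], x])[None, :]
    return _probs_from_eta(_eta_matrix(params.beta, row))[0]


def _observed_outcomes(cohort: pd.DataFrame) -> np.ndarray:
    y = cohort["category18"]
    if y.isna().any():
        bad = cohort.loc[y.isna(), "id"].tolist()
        raise ValueError(f"records without category18: ids {bad[:20]}")
    return y.to_numpy(dtype=int)


def loglik(params: ModelParams, cohort: pd.DataFrame) -> float:
    """Full multinomial log-likelihood sum_i log p_{y_i}(x_i)."""
    X = design_matrix(cohort)
    y = _observed_outcomes(cohort)
    eta = _eta_matrix(params.beta, X)
    logp = eta - logsumexp(eta, axis=1, keepdims=True)
    vals = logp[np.arange(len(y)), y - 1]
    if not np.all(np.isfinite(vals)):
        bad = cohort.loc[~np.isfinite(vals), "id"].tolist()
        raise FloatingPointError(f"log-probability underflow at ids {bad[:20]}")
    return float(vals.sum())


@dataclass
class FitResult:
    """A fitted coefficient table with its uncertainty.

    ``cov`` is the 18 x 18 inverse observed information for GMLE and a
    (3, 6, 6) stack of per-submodel covariances for SMLE (the separate-fit
    construction carries no cross-submodel covariance — that is what the
    bootstrap is for). ``loglik`` is always the full multinomial
    log-likelihood at ``params``.
    """

    params: ModelParams
    method: str
    cov: np.ndarray
    loglik: float
    iterations: int
    converged: bool

    def se(self) -> np.ndarray:
        """(3, 6) standard errors aligned with ``params.beta``."""
        if self.cov.ndim == 2:  # GMLE: 18 x 18
            return np.sqrt(np.diag(self.cov)).reshape(len(CATEGORIES), len(COLUMNS))
        return np.sqrt(np.array([np.diag(c) for c in self.cov]))


def _multinomial_loglik_flat(theta: np.ndarray, X: np.ndarray, y: np.ndarray, p: int) -> float:
    beta = theta.reshape(3, p)
    eta = np.zeros((X.shape[0], 4))
    eta[:, [0, 2, 3]] = X @ beta.T
    logp = eta - logsumexp(eta, axis=1, keepdims=True)
    return float(logp[np.arange(len(y)), y - 1].sum())


def _newton_multinomial(X, y, init, tol, max_iter):
    """Newton-Raphson with step-halving on the multinomial likelihood.

    Returns (beta (3, p), info (3p x 3p), loglik, iterations, converged).
    """
    n, p = X.shape
    codes = np.asarray(NONBASE_CODES)
    Y = (y[:, None] == codes[None, :]).astype(float)  # n x 3 indicators
    beta = init.copy()
    ll = _multinomial_loglik_flat(beta.ravel(), X, y, p)
    info = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.zeros((n, 4))
        eta[:, [0, 2, 3]] = X @ beta.T
        P4 = _probs_from_eta(eta)
        P = P4[:, [0, 2, 3]]  # n x 3, non-baseline
        grad = (X.T @ (Y - P)).T.ravel()  # flat, j-major (matches beta.ravel())
        if np.max(np.abs(grad)) < tol:
            converged = True
        info = np.empty((3 * p, 3 * p))
        for j in range(3):
            for k in range(j, 3):
                w = P[:, j] * ((1.0 if j == k else 0.0) - P[:, k])
                block = -(X.T @ (w[:, None] * X))
                info[j * p:(j + 1) * p, k * p:(k + 1) * p] = -block
                info[k * p:(k + 1) * p, j * p:(j + 1) * p] = -block.T
        if converged:
            break
        try:
            step = np.linalg.solve(info, grad).reshape(3, p)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular information matrix; consider rescaling predictors or "
                "checking for separation / collinearity"
            ) from None
        # step-halving: insist on non-decreasing log-likelihood
        scale = 1.0
        for _ in range(20):
            candidate = beta + scale * step
            ll_new = _multinomial_loglik_flat(candidate.ravel(), X, y, p)
            if ll_new >= ll - 1e-10:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = ll_new
    return beta, info, ll, it, converged


def fit_gmle(
    cohort: pd.DataFrame,
    init: ModelParams | str | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Global MLE of the baseline-category logit model by Newton-Raphson.

    ``init`` may be a :class:`ModelParams`, the string ``"smle"`` for a
    separate-fit warm start, or ``None`` for a zero start. Convergence is
    declared when the gradient max-norm falls below ``tol``; the covariance
    is the inverse observed information at the optimum.
    """
    X = design_matrix(cohort)
    y = _observed_outcomes(cohort)
    if len(np.unique(y)) < 2:
        raise ValueError("all records share one outcome category; model not identifiable")
    xtx_eigvals = np.linalg.eigvalsh(X.T @ X)
    if xtx_eigvals[0] <= xtx_eigvals[-1] * 1e-12:
        raise ValueError("design matrix is rank deficient")
    if init == "smle":
        start = fit_smle(cohort, tol=tol, max_iter=max_iter).params.beta
    elif isinstance(init, ModelParams):
        start = init.beta
    else:
        start = np.zeros((3, X.shape[1]))
    beta, info, ll, iters, converged = _newton_multinomial(X, y, start, tol, max_iter)
    cov = np.linalg.inv(info)
    return FitResult(ModelParams(beta), "GMLE", cov, ll, iters, converged)


def _newton_binary(X, y01, tol, max_iter):
    """IRLS/Newton for binary logistic regression; returns (beta, cov, it, conv)."""
    n, p = X.shape
    beta = np.zeros(p)
    ll = -n * np.log(2.0)
    info = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y01 - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
        w = mu * (1.0 - mu)
        info = X.T @ (w[:, None] * X)
        if converged:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular information in binary logistic fit; check for separation"
            ) from None
        scale = 1.0
        for _ in range(20):
            eta_new = X @ (beta + scale * step)
            ll_new = float(np.sum(y01 * eta_new - np.logaddexp(0.0, eta_new)))
            if ll_new >= ll - 1e-10:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = ll_new
    return beta, np.linalg.inv(info), it, converged


def fit_smle(cohort: pd.DataFrame, tol: float = 1e-8, max_iter: int = 100) -> FitResult:
    """Separate MLE: a binary logistic fit of j vs baseline per subpopulation.

    For each j in {1, 3, 4} the fit uses only records with follow-up category
    in {j, 2}. The reported ``loglik`` is the full multinomial log-likelihood
    at the assembled coefficient table (not the sum of the three binary
    likelihoods), so SMLE and GMLE are compared on the same scale.
    """
    X = design_matrix(cohort)
    y = _observed_outcomes(cohort)
    beta = np.zeros((3, X.shape[1]))
    covs = np.zeros((3, X.shape[1], X.shape[1]))
    iters = 0
    converged = True
    for row, j in enumerate(NONBASE_CODES):
        mask = (y == j) | (y == 2)
        y_sub = (y[mask] == j).astype(float)
        n_event = int(y_sub.sum())
        if n_event == 0 or n_event == mask.sum():
            raise ValueError(
                f"subpopulation {{{j}, 2}} is degenerate (categories {j} and 2 "
                "must both be present)"
            )
        b, c, it, conv = _newton_binary(X[mask], y_sub, tol, max_iter)
        beta[row] = b
        covs[row] = c
        iters = max(iters, it)
        converged = converged and conv
    params = ModelParams(beta)
    return FitResult(params, "SMLE", covs, loglik(params, cohort), iters, converged)


def wald_or_intervals(fit: FitResult, alpha: float = 0.05) -> pd.DataFrame:
    """Per-coefficient Wald intervals and adjusted odds-ratio intervals.

    One row per (category, term): the point estimate with its
    ``(1 - alpha)`` Wald interval, and for slope terms the adjusted OR
    ``exp(estimate)`` with interval given by exponentiating the coefficient
    bounds. Intercept rows carry no OR.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; intervals would be unreliable")
    z = norm.ppf(1.0 - alpha / 2.0)
    se = fit.se()
    rows = []
    for r, cat in enumerate(CATEGORIES):
        for c, term in enumerate(COLUMNS):
            est = fit.params.beta[r, c]
            lo, hi = est - z * se[r, c], est + z * se[r, c]
            is_slope = term != "intercept"
            rows.append(
                {
                    "category": cat,
                    "term": term,
                    "estimate": est,
                    "se": se[r, c],
                    "ci_low": lo,
                    "ci_high": hi,
                    "or_value": np.exp(est) if is_slope else np.nan,
                    "or_low": np.exp(lo) if is_slope else np.nan,
                    "or_high": np.exp(hi) if is_slope else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class BootstrapResult:
    """Case-resampling bootstrap of the 18 coefficients."""

    B: int
    method: str
    estimates: np.ndarray  # B_ok x 18 (failed replicates dropped)
    means: np.ndarray
    sds: np.ndarray
    corr: np.ndarray  # 18 x 18 correlation of the estimates
    n_failed: int

    def corr_entry(self, category_a: str, term_a: str, category_b: str, term_b: str) -> float:
        ia = CATEGORIES.index(category_a) * len(COLUMNS) + COLUMNS.index(term_a)
        ib = CATEGORIES.index(category_b) * len(COLUMNS) + COLUMNS.index(term_b)
        return float(self.corr[ia, ib])


def bootstrap_params(
    cohort: pd.DataFrame, B: int, seed: int, method: str = "smle"
) -> BootstrapResult:
    """Resample records with replacement at full size and refit ``B`` times.

    The product is the joint sampling distribution of all 18 coefficients —
    in particular the 18 x 18 correlation matrix, which the separate-fit
    covariance construction cannot provide. Replicates whose fit fails are
    skipped and counted; more than 10% failures is an error.
    """
    if B < 2:
        raise ValueError("B must be at least 2 to form correlations")
    fitter = {"smle": fit_smle, "gmle": fit_gmle}.get(method.lower())
    if fitter is None:
        raise ValueError(f"unknown method {method!r}; use 'smle' or 'gmle'")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    estimates = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sample = cohort.iloc[idx].reset_index(drop=True)
        try:
            estimates.append(fitter(sample).params.flat())
        except (ValueError, np.linalg.LinAlgError, FloatingPointError):
            n_failed += 1
    if n_failed > 0.1 * B:
        raise RuntimeError(f"bootstrap: {n_failed} of {B} replicate fits failed")
    est = np.asarray(estimates)
    return BootstrapResult(
        B=B,
        method=method.lower(),
        estimates=est,
        means=est.mean(axis=0),
        sds=est.std(axis=0, ddof=1),
        corr=np.corrcoef(est, rowvar=False),
        n_failed=n_failed,
    )
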