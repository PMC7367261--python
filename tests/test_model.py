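"""The baseline-category logit core: probabilities, likelihood, SMLE/GMLE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize

import bmitrans as bt
from bmitrans.model import (
    ModelParams,
    _multinomial_loglik_flat,
    _newton_multinomial,
    design_matrix,
    probability_matrix,
)

REFERENCE_X = (1, 1, 8, 130, 20)
# category probabilities at REFERENCE_X under the packaged reference SMLE
# coefficients, frozen from direct evaluation of the category-probability
# formula: eta = (-6.04, 0, 0.25, 0.20)
REFERENCE_PROBS = (0.000679, 0.285078, 0.366048, 0.348195)


class TestCategoryProbs:
    def test_zero_coefficients_are_uniform(self):
        assert np.allclose(bt.category_probs(ModelParams.zeros(), REFERENCE_X), 0.25)

    def test_reference_point(self, truth_params):
        probs = bt.category_probs(truth_params, REFERENCE_X)
        assert probs == pytest.approx(REFERENCE_PROBS, abs=5e-6)

    def test_huge_intercept_drives_probability_to_one(self):
        beta = np.zeros((3, 6))
        beta[2, 0] = 600.0
        probs = bt.category_probs(ModelParams(beta), REFERENCE_X)
        assert probs[3] == pytest.approx(1.0, abs=1e-12)

    @given(
        beta=st.lists(st.floats(-3, 3), min_size=18, max_size=18),
        x=st.tuples(
            st.integers(0, 1),
            st.integers(0, 1),
            st.integers(6, 11),
            st.floats(100, 180),
            st.floats(10, 35),
        ),
    )
    def test_normalisation(self, beta, x):
        """Probabilities sum to 1 within 1e-12 and stay in [0, 1]; they are
        strictly interior whenever the linear predictors are moderate (large
        |eta| saturates in floating point by design)."""
        params = ModelParams.from_flat(beta)
        probs = bt.category_probs(params, x)
        assert abs(probs.sum() - 1.0) < 1e-12
        assert np.all(probs >= 0) and np.all(probs <= 1)
        eta = params.beta @ np.concatenate([[1.0], np.asarray(x, dtype=float)])
        if np.abs(eta).max() < 30:
            assert np.all(probs > 0) and np.all(probs < 1)


class TestLoglik:
    def test_single_record_null_model(self):
        frame = pd.DataFrame(
            {"id": [1], "gender": [1], "district": [0], "age": [7],
             "height": [120.0], "bmi13": [16.0], "category13": [2],
             "category18": pd.array([2], dtype="Int64")}
        )
        assert bt.loglik(ModelParams.zeros(), frame) == pytest.approx(np.log(0.25))

    def test_equals_sum_of_per_record_log_probs(self, truth_params, cohort_small):
        probs = probability_matrix(truth_params, cohort_small)
        y = cohort_small["category18"].to_numpy(dtype=int)
        manual = np.log(probs[np.arange(len(y)), y - 1]).sum()
        assert bt.loglik(truth_params, cohort_small) == pytest.approx(manual)

    def test_average_loglik_approximates_negative_entropy(self, truth_params):
        """At the generating truth, the mean per-record log-likelihood
        estimates minus the model's conditional entropy."""
        coh = bt.generate_cohort(bt.CohortConfig(n=100000, seed=77), params=truth_params)
        probs = probability_matrix(truth_params, coh)
        neg_entropy = float((probs * np.log(probs)).sum(axis=1).mean())
        avg_ll = bt.loglik(truth_params, coh) / len(coh)
        assert avg_ll == pytest.approx(neg_entropy, abs=0.01)


def _direct_maximizer(X, y, n_params):
    """Independent oracle: restarted adaptive Nelder-Mead on the likelihood."""
    def neg(theta):
        return -_multinomial_loglik_flat(theta, X, y, X.shape[1])

    x = np.zeros(n_params)
    for _ in range(15):
        res = minimize(
            neg, x, method="Nelder-Mead",
            options={"maxiter": 50000, "maxfev": 50000, "xatol": 1e-9,
                     "fatol": 1e-13, "adaptive": True},
        )
        if np.allclose(res.x, x, atol=1e-10):
            break
        x = res.x
    return x


class TestGmle:
    def test_matches_direct_maximization_on_tiny_instance(self, tiny_multinomial_instance):
        X, y = tiny_multinomial_instance
        beta, _, _, _, converged = _newton_multinomial(X, y, np.zeros((3, 3)), 1e-10, 100)
        assert converged
        oracle = _direct_maximizer(X, y, 9)
        assert np.abs(beta.ravel() - oracle).max() < 1e-4

    def test_recovers_truth_within_wald_intervals(self, truth_params, cohort_medium):
        """Most true coefficients fall inside their 95% Wald intervals."""
        fit = bt.fit_gmle(cohort_medium)
        assert fit.converged
        se = fit.se()
        z = np.abs(fit.params.beta - truth_params.beta) / se
        assert (z < 1.96).mean() > 0.8

    def test_single_category_not_identifiable(self, cohort_small):
        degenerate = cohort_small.copy()
        degenerate["category18"] = pd.array([4] * len(degenerate), dtype="Int64")
        with pytest.raises(ValueError, match="identifiable"):
            bt.fit_gmle(degenerate)

    def test_smle_warm_start_agrees_with_cold_start(self, cohort_small):
        cold = bt.fit_gmle(cohort_small)
        warm = bt.fit_gmle(cohort_small, init="smle")
        assert np.abs(cold.params.beta - warm.params.beta).max() < 1e-6


class TestSmle:
    def test_submodels_match_reference_binary_fits(self, cohort_small):
        """Each separate fit equals an independent binary logistic fit on the
        same {j, 2} subpopulation to 1e-6."""
        sm_api = pytest.importorskip("statsmodels.api")
        fit = bt.fit_smle(cohort_small)
        X = design_matrix(cohort_small)
        y = cohort_small["category18"].to_numpy(dtype=int)
        for row, j in enumerate((1, 3, 4)):
            mask = (y == j) | (y == 2)
            ref = sm_api.Logit((y[mask] == j).astype(float), X[mask]).fit(
                disp=0, method="newton", tol=1e-10
            )
            assert np.abs(ref.params - fit.params.beta[row]).max() < 1e-6

    def test_null_data_gives_null_slopes(self):
        """Outcomes independent of x: every slope within 3 SEs of zero."""
        rng = np.random.default_rng(8)
        base = bt.generate_baseline(bt.CohortConfig(n=8000, seed=21))
        base["category18"] = pd.array(rng.integers(1, 5, len(base)), dtype="Int64")
        fit = bt.fit_smle(base)
        z = np.abs(fit.params.beta[:, 1:]) / fit.se()[:, 1:]
        assert z.max() < 3.5

    def test_degenerate_subpopulation_names_category(self, cohort_small):
        broken = cohort_small.copy()
        y = broken["category18"].to_numpy(dtype=int)
        y[y == 1] = 2  # erase all follow-up underweight
        broken["category18"] = pd.array(y, dtype="Int64")
        with pytest.raises(ValueError, match="1"):
            bt.fit_smle(broken)


def test_gmle_dominates_smle_loglik(cohort_small, cohort_medium):
    """The joint maximizer can never have a lower full log-likelihood than
    the assembled separate fits."""
    for coh in (cohort_small, cohort_medium):
        s = bt.fit_smle(coh)
        g = bt.fit_gmle(coh)
        assert s.converged and g.converged
        assert g.loglik >= s.loglik - 1e-8


def test_fitted_probabilities_invariant_to_predictor_shift(cohort_small):
    """Adding a constant to a predictor column changes only intercepts;
    fitted probabilities are unchanged."""
    shifted = cohort_small.copy()
    shifted["height"] = shifted["height"] + 25.0
    for fitter in (bt.fit_smle, bt.fit_gmle):
        fit_a = fitter(cohort_small)
        fit_b = fitter(shifted)
        pa = probability_matrix(fit_a.params, cohort_small)
        pb = probability_matrix(fit_b.params, shifted)
        assert np.abs(pa - pb).max() < 1e-8
        assert np.abs(fit_a.params.beta[:, 1:] - fit_b.params.beta[:, 1:]).max() < 1e-6


class TestWaldOrIntervals:
    def test_or_bounds_are_exp_of_coefficient_bounds(self, cohort_small):
        table = bt.wald_or_intervals(bt.fit_smle(cohort_small))
        slopes = table[table["term"] != "intercept"]
        assert np.allclose(slopes["or_low"], np.exp(slopes["ci_low"]))
        assert np.allclose(slopes["or_high"], np.exp(slopes["ci_high"]))
        # the reference presentation: a coefficient CI of (0.34, 0.44) maps to
        # an adjusted-OR CI of (1.40, 1.55); (-1.00, -0.93) maps to (0.37, 0.39)
        assert np.exp([0.34, 0.44]) == pytest.approx([1.40, 1.55], abs=5e-3)
        assert np.exp([-1.00, -0.93]) == pytest.approx([0.3679, 0.3946], abs=5e-4)

    def test_zero_coefficient_interval_contains_one(self):
        frame = bt.generate_cohort(bt.CohortConfig(n=3000, seed=44), params=bt.ModelParams.zeros())
        table = bt.wald_or_intervals(bt.fit_smle(frame))
        gender_rows = table[table["term"] == "gender"]
        assert ((gender_rows["or_low"] < 1.0) & (gender_rows["or_high"] > 1.0)).all()


class TestBootstrap:
    def test_deterministic_under_seed(self, cohort_small):
        a = bt.bootstrap_params(cohort_small, B=5, seed=31)
        b = bt.bootstrap_params(cohort_small, B=5, seed=31)
        assert np.array_equal(a.estimates, b.estimates)

    def test_rejects_single_replicate(self, cohort_small):
        with pytest.raises(ValueError, match="B"):
            bt.bootstrap_params(cohort_small, B=1, seed=1)

    def test_sds_consistent_with_wald_ses(self, cohort_medium):
        """Bootstrap SDs agree with the asymptotic (Wald) standard errors to
        within 25% for all 18 coefficients."""
        boot = bt.bootstrap_params(cohort_medium, B=200, seed=17, method="smle")
        wald_se = bt.fit_smle(cohort_medium).se().ravel()
        ratio = boot.sds / wald_se
        assert boot.n_failed == 0
        assert np.all(ratio > 0.75) and np.all(ratio < 1.25)
        # correlation matrix sanity: symmetric, unit diagonal, bounded
        assert np.allclose(boot.corr, boot.corr.T)
        assert np.allclose(np.diag(boot.corr), 1.0)
        assert np.all(np.abs(boot.corr) <= 1.0 + 1e-12)
        # age and height estimates are strongly negatively correlated per row,
        # the qualitative structure the bootstrap exists to expose
        for cat in ("underweight", "overweight", "obese"):
            assert boot.corr_entry(cat, "age", cat, "height") < -0.4
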