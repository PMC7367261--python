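# Methods

## Model and estimation

The outcome is the follow-up nutrition category J ∈ {1, 2, 3, 4}
(underweight, normal, overweight, obese) of a child observed five years
after baseline. The baseline-category logit model sets, with "normal" as
reference,

    log[ p_j(x) / p_2(x) ] = β_{j,0} + Σ_{i=1..5} β_{j,i} x_i ,  j ∈ {1, 3, 4},

with x = (gender, district, age, height, bmi13): gender 1 = male,
district 1 = urban, age in integer years 6–11, height in cm, baseline BMI in
kg/m². Weight is excluded because BMI already encodes weight/height². The
model assumes independence across children (no school clustering or spatial
correlation) and linear, interaction-free predictor effects; the empirical
obese:normal log-ratio profile over (age, BMI) bins
(`tables.logratio_profile`) is the diagnostic supporting additivity.

**SMLE.** For each j ∈ {1, 3, 4} a binary logistic regression of category j
versus "normal" is fitted on the subpopulation with outcome in {j, 2}. The
conditional log-odds of j against the reference coincide with the
multinomial linear predictor, so the assembled 3 × 6 table consistently
estimates β. Each binary fit uses Newton/IRLS with step-halving (up to 20
halvings), convergence at gradient max-norm < 1e-8, max 100 iterations.

**GMLE.** Newton–Raphson on the full 18-parameter multinomial likelihood.
Analytic gradient X'(Y_j − P_j) and blockwise observed information
X' diag(P_j(δ_jk − P_k)) X; step-halving as above; zero start by default
with an optional SMLE warm start; covariance is the inverse observed
information at the optimum. Category probabilities are evaluated with
max-subtracted softmax, stable to |η| ≈ 700. The reported log-likelihood of
*both* estimators is the full multinomial log-likelihood at the assembled
parameters, so GMLE ≥ SMLE holds on every dataset where both converge (this
ordering is asserted in the tests).

The SMLE covariance is reported per submodel, a (3, 6, 6) stack: the
separate-fit construction carries no cross-submodel information. The joint
18 × 18 correlation structure is instead obtained from a case bootstrap
(records resampled with replacement at full cohort size; replicates whose
refit fails are dropped and counted, > 10% failures is an error). On
default synthetic cohorts the bootstrap reproduces the strong negative
age–height coefficient correlations (≈ −0.6 to −0.8 per category) that
motivate the bootstrap in the first place.

**Proportional-odds score test.** A natural question is whether a cumulative
logit with one shared slope vector would suffice. The constrained model
logit P(Y ≤ k | x) = α_k + x'γ is fitted by L-BFGS on a parametrisation
(α_1, log Δ_2, log Δ_3, γ) that keeps cutpoints ordered, with analytic
gradient; predictors are standardised internally (the score statistic is
invariant under this linear reparametrisation). The Rao statistic
U' I⁻¹ U uses the analytic unconstrained score and an observed information
obtained by central differences of that score (step 1e-5·max(1, |θ|)); df =
(K − 2)·p = 10. Simulation at a proportional-odds truth (n = 5,000, 500
replicates) shows type-I error ≈ 0.03–0.05 at α = 0.05; data generated from
the reference transition coefficients reject at p < 1e-40 for n = 20,000.

## Descriptive epidemiology

Transition tables are plain 4 × 4 cross-tabulations with margins. Reporting
convention for percentages: whole percent, one decimal below 1%, rounding
half away from zero; ratios to two decimals. Odds-ratio intervals are Woolf
(log-scale Wald, variance 1/a + 1/b + 1/c + 1/d); zero cells raise unless
the optional +0.5 continuity mode is enabled. The change in a category's
prevalence between the two waves of the *same* children uses the paired
Wald variance [p_row + p_col − 2·p_diag − d²]/n, where p_diag is the joint
diagonal proportion; a multinomial parametric bootstrap (B = 10,000) agrees
within 0.005 in the tests. Exact z-quantiles (1.959964…) are used
throughout, not 1.96.

A note on one published bound: recomputing the boys-vs-girls obese odds
ratio in the baseline-underweight stratum from the published counts gives a
Woolf lower bound of 1.67 where 1.66 was printed; the original interval
method is unstated, the upper bound matches, and the discrepancy is left as
is.

## Prediction and evaluation

Prediction is the discriminant rule: argmax over {η_1, 0, η_3, η_4},
equivalent to the maximal category probability; exact ties break to the
lowest category index and are flagged. Sensitivity is row-wise recall;
**specificity is column-wise precision** (of the children predicted in a
category, the share observed in it) — deliberately so, because that is the
convention of the classification tables this package mirrors, and it
differs from the textbook true-negative rate. Cross-validation stratifies
folds on the follow-up category (scikit-learn's StratifiedKFold drives the
fold construction) so the rare underweight class appears in every fold;
test predictions are pooled over the k folds within a repeat, giving one
accuracy per repeat, and the SD is across repeats. ROC curves are traced at
unique score thresholds; AUC is the Mann–Whitney statistic with half credit
for ties, computed from average ranks and verified against exhaustive pair
counting. The model-expected transition table sums predicted probabilities
within baseline categories, so its rows match observed baseline totals
exactly.

## High-risk domains and projection

Pr(obese) is increasing in BMI whenever the obese-row BMI coefficient
weakly dominates all rows' (including the baseline's zero) — checked before
any boundary construction; the default coefficients satisfy it, and
numerically Pr(obese) is also increasing in height and decreasing in age
over the screened ranges. The boundary search runs bisection per grid
height (default 110–170 cm, step 1 cm) over BMI ∈ [10, 35], stopping when
the probability bracket is narrower than tol = 1e-6 and returning the upper
endpoint, so returned points satisfy threshold ≤ Pr < threshold + tol. The
threshold comparison is ≥ (the "strictly greater" reading differs on a
measure-zero set). Projections apply exactly one five-year transition step
— mean predicted probabilities per stratum — and deliberately do not
iterate further, since the coefficients themselves may drift over calendar
time.

## The synthetic cohort generator

Real two-wave survey records are confidential, so the generator emulates
their structure: gender, district and age are independent draws with
defaults equal to the exact baseline margins of the motivating cohort
(51.13% boys, 55.66% urban, age distribution over 6–11 from the published
counts — the published rounded percentages sum to 101%, so the exact count
ratios are used instead); height ~ N(100 + 6·age + 2·gender, 7) cm and
bmi13 ~ N(14.5 + 0.45·age + 0.5·gender, 2.5) kg/m², truncated to [10, 35]
by rejection (max 1,000 redraw rounds, no boundary atoms). Follow-up
categories are sampled from the transition model at the packaged reference
coefficients. Baseline categories come from a packaged **synthetic,
non-normative** cutoff table (linear in age with a gender offset, placed to
give roughly 3.6 / 65.5 / 15.0 / 15.9% baseline mass); real analyses must
supply the applicable national cutoffs, which are not redistributable here.

What the generator does *not* emulate: the real joint covariate
distribution (its heights are taller and its BMI tails thinner than a real
cohort's), school-level clustering, missingness, and measurement error.
Consequently passing tests demonstrate correctness of the estimators and
pipeline on data of the right structure, not that any synthetic prevalence
matches the real population. One concrete consequence: under these defaults
the follow-up underweight category is rare (~0.5%), so underweight-row
coefficients are estimated with sampling SDs near 0.1 even at n = 88,980 —
parameter-recovery checks therefore use standard-error-scaled bands for
that row, while the well-identified overweight and obese rows recover
within ±0.05 absolute at study scale.

## Problem sizes used in tests and acceptance

Unit tests run on cohorts of 4,000–20,000; the entropy and
sampling-correctness checks use 100,000 draws at a single predictor vector;
recovery checks simulate at the study scale n = 88,980; score-test
calibration uses 500 replicates at n = 5,000 in the test suite and 200 in
the acceptance script; bootstrap-vs-Wald agreement uses B = 200 at
n = 20,000. These sizes were chosen so every statistical band is meaningful
at the stated tolerances while the whole suite stays fast.

## Known limitations

Integer ages only (no month resolution); WHO/IOTF cutoff systems are out of
scope; no penalised or Bayesian estimation and no interaction terms; no
uncertainty bands on risk boundaries; single-step projections only.
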