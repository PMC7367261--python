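# bmitrans

Five-year BMI-category transition modelling for school-age cohorts.

## The problem

Large two-wave school surveys measure each child's gender, district
(urban/rural), age, height and BMI at a baseline examination and record the
child's nutrition category — underweight (1), normal (2), overweight (3),
obese (4) — at a follow-up examination five years later. Public-health teams
want three things from such data: the empirical 4 × 4 transition structure
between categories, a predictive model quantifying each child's probability
of every future category from today's measurements, and a concrete screening
rule that flags the children at highest obesity risk for early intervention.
`bmitrans` implements this workflow for biostatisticians and epidemiologists
working with cohorts of this shape, together with a synthetic cohort
generator so every stage is testable without access to any confidential
survey data.

## The model

With p_j(x) the probability of landing in category j given baseline
predictors x = (gender, district, age, height, BMI), the core is the
baseline-category logit model with "normal" as the reference:

    log[ p_j(x) / p_2(x) ] = β_{j,0} + Σ_i β_{j,i} x_i ,   j ∈ {1, 3, 4}

so p_2(x) = 1 / (1 + Σ_j e^{η_j}) and p_j(x) = e^{η_j} p_2(x). Two
estimators are provided and compared:

* **SMLE** (separate maximum likelihood): each non-reference category j is
  fitted as an ordinary binary logistic regression of j against "normal" on
  the subpopulation whose outcome is in {j, 2}. Three simple fits, no
  special software, consistent for the multinomial parameters.
* **GMLE** (global maximum likelihood): Newton–Raphson on the full
  18-parameter multinomial likelihood. Its log-likelihood weakly dominates
  SMLE's by construction, and on large cohorts the two coefficient tables
  agree closely.

Around the model core the package provides transition tables with Woolf
odds-ratio intervals and the paired (marginal-homogeneity) Wald interval for
prevalence change, the argmax discriminant prediction rule with stratified
repeated cross-validation and Mann–Whitney ROC/AUC, a proportional-odds
score test (df = 10) justifying the unconstrained model over a cumulative
logit, a case bootstrap for the joint 18-coefficient correlation structure,
and bisection-built high-risk (height, BMI) decision boundaries at a
probability threshold.

## Worked example

```python
import bmitrans as bt

cohort = bt.generate_cohort(bt.CohortConfig(n=20000, seed=1))
smle, gmle = bt.fit_smle(cohort), bt.fit_gmle(cohort)
print(round(smle.loglik, 1), round(gmle.loglik, 1))   # -18084.7 -18083.6
print(bt.category_probs(smle.params, (1, 1, 8, 130, 20)).round(3))
score = bt.po_score_test(cohort)
print(round(score.statistic, 1), score.df)            # 229.3 10
```

The log-likelihoods illustrate the SMLE/GMLE ordering (the global fit is
never worse); the probability vector at a urban 8-year-old boy of 130 cm and
BMI 20 spells out his four category probabilities five years ahead; the
score statistic of 229.3 on 10 degrees of freedom rejects proportional odds
decisively, confirming that the per-category slopes really differ.

The same workflow as scripts, each writing its tables under `results/`:

```bash
python analysis/01_simulate_cohort.py --n 20000 --seed 1
python analysis/02_descriptive_transitions.py
python analysis/03_fit_transition_model.py --bootstrap 100
python analysis/04_evaluate_predictions.py
python analysis/05_risk_screening.py
```

Step 02 reproduces the printed descriptive epidemiology from the packaged
published transition counts — 65% of the baseline-obese group is still
obese at follow-up, the boys-vs-girls obese odds-ratio intervals reach
upper bounds 3.90 / 1.99 / 1.50 / 1.64 across the four baseline strata, and
the obesity prevalence drop has 95% CI (0.02, 0.03). Step 04 shows the
fitted model beating the crude assign-everyone-"normal" baseline (58.0% vs
44.8% accuracy on the simulated cohort, five-fold CV within 0.1 pp of the
training accuracy). Step 05 prints the screening boundary climbing with age:
at threshold 0.9 the lowest flagged BMI for urban boys rises from 22.8
(age 6) to 32.2 (age 11).

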