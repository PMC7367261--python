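"""Category prediction and its evaluation.

The prediction rule is the discriminant rule of the baseline-category logit
model: assign the category with the largest predicted probability,
equivalently the largest linear predictor among {eta_1, 0, eta_3, eta_4}.
Evaluation covers the 4 x 4 confusion matrix with per-category sensitivity
and specificity, repeated stratified k-fold cross-validation, per-submodel
ROC/AUC, and the model-expected transition table.

Definition note — specificity here is column-wise (precision-like): of the
children *predicted* to be in a category, the fraction actually observed in
it. This differs from the usual true-negative-rate definition but is the
convention of the classification tables this package mirrors; sensitivity
is the usual row-wise recall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .model import (
    FitResult,
    ModelParams,
    design_matrix,
    _eta_matrix,
    _observed_outcomes,
    fit_gmle,
    fit_smle,
    probability_matrix,
)
from .tables import TransitionTable


class Prediction(NamedTuple):
    category: int
    tie: bool


def predict_category(params: ModelParams, x) -> Prediction:
    """Predicted category at one predictor vector, with a tie flag.

    Ties (exactly equal maximal linear predictors) break toward the lowest
    category index.
    """
    x = np.asarray(x, dtype=float)
    row = np.concatenate([[1.0], x])[None, :]
    eta = _eta_matrix(params.beta, row)[0]
    best = int(np.argmax(eta))  # argmax returns the first maximal index
    tie = bool((eta == eta[best]).sum() > 1)
    return Prediction(category=best + 1, tie=tie)


def predict_cohort(params: ModelParams, cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised discriminant rule; returns (categories, tie flags)."""
    eta = _eta_matrix(params.beta, design_matrix(cohort))
    cats = np.argmax(eta, axis=1) + 1
    ties = (eta == eta.max(axis=1, keepdims=True)).sum(axis=1) > 1
    return cats.astype(int), ties


@dataclass
class ClassificationReport:
    """Confusion matrix (rows observed, columns predicted) with per-category
    sensitivity (row-wise recall), specificity (column-wise precision) and
    overall accuracy (trace / total)."""

    confusion: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    overall_accuracy: float


def classification_report(observed, predicted) -> ClassificationReport:
    observed = np.asarray(observed, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if len(observed) == 0:
        raise ValueError("empty input")
    for arr, name in ((observed, "observed"), (predicted, "predicted")):
        if arr.min() < 1 or arr.max() > 4:
            raise ValueError(f"{name} categories must be in 1..4")
    confusion = np.zeros((4, 4), dtype=int)
    np.add.at(confusion, (observed - 1, predicted - 1), 1)
    diag = np.diag(confusion).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sensitivity = diag / confusion.sum(axis=1)
        specificity = diag / confusion.sum(axis=0)
    return ClassificationReport(
        confusion=confusion,
        sensitivity=sensitivity,
        specificity=specificity,
        overall_accuracy=float(diag.sum() / len(observed)),
    )


@dataclass
class CVSummary:
    """Repeated stratified k-fold cross-validation summary. Per repeat, test
    predictions are pooled over the k folds before scoring, so the SD is
    across repeats."""

    k: int
    repeats: int
    seed: int
    accuracy_mean: float
    accuracy_sd: float
    sensitivity_means: np.ndarray
    specificity_means: np.ndarray
    accuracies: np.ndarray


_FITTERS = {"smle": fit_smle, "gmle": fit_gmle}


def cross_validate(
    cohort: pd.DataFrame, k: int = 5, repeats: int = 100, seed: int = 0, method: str = "smle"
) -> CVSummary:
    """Repeated k-fold CV stratified on the follow-up category.

    Each repeat reshuffles the stratified folds, refits the model on every
    training fold by ``method`` and predicts its test fold; the pooled
    predictions give one accuracy (and per-category sensitivities /
    specificities) per repeat.
    """
    fitter = _FITTERS.get(method.lower())
    if fitter is None:
        raise ValueError(f"unknown method {method!r}; use 'smle' or 'gmle'")
    y = _observed_outcomes(cohort)
    counts = pd.Series(y).value_counts()
    too_small = counts[counts < k]
    if len(too_small):
        raise ValueError(
            f"categories {sorted(too_small.index)} have fewer than k={k} members; "
            "stratified folds are impossible"
        )
    rng = np.random.default_rng(seed)
    accuracies = np.empty(repeats)
    sens = np.empty((repeats, 4))
    spec = np.empty((repeats, 4))
    for r in range(repeats):
        splitter = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        predicted = np.empty(len(cohort), dtype=int)
        for train_idx, test_idx in splitter.split(np.zeros(len(cohort)), y):
            fit = fitter(cohort.iloc[train_idx].reset_index(drop=True))
            predicted[test_idx], _ = predict_cohort(fit.params, cohort.iloc[test_idx])
        report = classification_report(y, predicted)
        accuracies[r] = report.overall_accuracy
        sens[r] = report.sensitivity
        spec[r] = report.specificity
    with warnings.catch_warnings():
        # a category never predicted in any repeat gives an all-NaN column
        warnings.simplefilter("ignore", RuntimeWarning)
        sens_means = np.nanmean(sens, axis=0)
        spec_means = np.nanmean(spec, axis=0)
    return CVSummary(
        k=k,
        repeats=repeats,
        seed=seed,
        accuracy_mean=float(accuracies.mean()),
        accuracy_sd=float(accuracies.std(ddof=1)) if repeats > 1 else 0.0,
        sensitivity_means=sens_means,
        specificity_means=spec_means,
        accuracies=accuracies,
    )


def roc_auc(binary_labels, scores) -> tuple[np.ndarray, float]:
    """ROC curve and AUC for one binary submodel.

    The ROC is traced over thresholds at the unique score values; the AUC is
    the Mann-Whitney probability that a positive outscores a negative, with
    half credit for ties (computed from average ranks, so it matches
    exhaustive pair counting exactly).
    """
    y = np.asarray(binary_labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    last_of_value = np.r_[ss[1:] != ss[:-1], True]
    tpr = np.r_[0.0, tps[last_of_value] / n_pos]
    fpr = np.r_[0.0, fps[last_of_value] / n_neg]
    return np.column_stack([fpr, tpr]), float(auc)


def submodel_roc(params: ModelParams, cohort: pd.DataFrame, j: int) -> tuple[np.ndarray, float]:
    """ROC of category ``j`` vs the baseline on the {j, 2} subpopulation,
    scored by the submodel linear predictor (the three separate-fit views
    of the full model)."""
    if j not in (1, 3, 4):
        raise ValueError("j must be a non-baseline category: 1, 3 or 4")
    y = _observed_outcomes(cohort)
    mask = (y == j) | (y == 2)
    if mask.sum() == 0:
        raise ValueError(f"no records in subpopulation {{{j}, 2}}")
    row = {1: 0, 3: 1, 4: 2}[j]
    scores = design_matrix(cohort.loc[mask]) @ params.beta[row]
    return roc_auc((y[mask] == j).astype(int), scores)


def expected_transition_table(params: ModelParams, cohort: pd.DataFrame) -> TransitionTable:
    """Model-expected 4 x 4 table: cell (a, b) sums the predicted probability
    of follow-up category ``b`` over children with baseline category ``a``.
    Rows therefore reproduce the observed baseline totals exactly."""
    probs = probability_matrix(params, cohort)
    counts = np.zeros((4, 4))
    cat13 = cohort["category13"].to_numpy(dtype=int)
    for a in range(1, 5):
        counts[a - 1] = probs[cat13 == a].sum(axis=0)
    return TransitionTable(counts, "model-expected")


def crude_all_normal_report(cohort: pd.DataFrame) -> ClassificationReport:
    """The crude baseline: predict "normal" for everyone (the rule the model
    must beat; its accuracy is just the follow-up share of normals)."""
    y = _observed_outcomes(cohort)
    return classification_report(y, np.full(len(y), 2))


def evaluate_fit(fit: FitResult, cohort: pd.DataFrame) -> ClassificationReport:
    """In-sample classification report of a fitted model's argmax rule."""
    predicted, _ = predict_cohort(fit.params, cohort)
    return classification_report(_observed_outcomes(cohort), predicted)
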