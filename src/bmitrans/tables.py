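"""Contingency-table epidemiology on 4 x 4 BMI-category transition matrices.

Builds baseline-to-follow-up cross-tabulations (overall or stratified),
row-percentage summaries under the reporting convention used in the field
(integers, one decimal below 1%, half-away-from-zero), Woolf confidence
intervals for 2 x 2 odds ratios, and the Wald interval for the change in a
category's marginal prevalence between the two waves of the same children
(the paired variance subtracts twice the joint diagonal cell, accounting for
within-child correlation).

The published transition counts of the motivating cohort ship with the
package (:func:`reference_transition_tables`) so the descriptive statistics
can be recomputed from the printed tables without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

CATEGORY_NAMES = ("underweight", "normal", "overweight", "obese")


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (the tabulation convention; numpy rounds
    half to even)."""
    factor = 10.0 ** decimals
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def display_percent(p):
    """Percentage for reporting: one decimal below 1%, else whole percent."""
    p = np.asarray(p, dtype=float)
    fine = round_half_away(p, 1)
    coarse = round_half_away(p, 0)
    out = np.where(p < 1.0, fine, coarse)
    return float(out) if out.ndim == 0 else out


@dataclass
class TransitionTable:
    """4 x 4 counts of (baseline category, follow-up category) with margins.

    ``counts[a - 1, b - 1]`` is the number of children in category ``a`` at
    baseline and ``b`` at follow-up. Cells may be real-valued for
    model-expected tables.
    """

    counts: np.ndarray
    stratum_label: str = "overall"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (4, 4):
            raise ValueError("counts must be 4 x 4")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        self.counts = counts

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.counts.sum())

    def row_percentages(self, rounded: bool = True) -> np.ndarray:
        """Percent of each baseline category ending in each follow-up
        category; rounded per the reporting convention unless disabled."""
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / self.row_totals[:, None]
        return display_percent(pct) if rounded else pct

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(CATEGORY_NAMES, name="category13"),
            columns=pd.Index(CATEGORY_NAMES, name="category18"),
        )


def crosstab(cohort: pd.DataFrame, stratify_by: str | None = None) -> list[TransitionTable]:
    """Cross-tabulate category13 against category18.

    Returns one :class:`TransitionTable` overall, or one per level of the
    ``stratify_by`` column (labelled ``"column=value"``). Every record must
    carry both categories.
    """
    if cohort["category18"].isna().any() if len(cohort) else False:
        bad = cohort.loc[cohort["category18"].isna(), "id"].tolist()
        raise ValueError(f"records without category18: ids {bad[:20]}")

    def _table(frame: pd.DataFrame, label: str) -> TransitionTable:
        counts = np.zeros((4, 4))
        if len(frame):
            ct = pd.crosstab(frame["category13"], frame["category18"].astype(int))
            ct = ct.reindex(index=[1, 2, 3, 4], columns=[1, 2, 3, 4], fill_value=0)
            counts = ct.to_numpy(dtype=float)
        return TransitionTable(counts, label)

    if stratify_by is None:
        return [_table(cohort, "overall")]
    return [
        _table(group, f"{stratify_by}={level}")
        for level, group in cohort.groupby(stratify_by, sort=True)
    ]


@dataclass
class ORResult:
    """A 2 x 2 odds ratio with its Woolf (log-scale Wald) interval."""

    or_value: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float
    alpha: float


def odds_ratio_ci(a, b, c, d, alpha: float = 0.05, continuity: bool = False) -> ORResult:
    """Woolf interval for the odds ratio of a 2 x 2 table.

    Layout: group 1 has ``a`` events / ``b`` non-events, group 2 has ``c``
    events / ``d`` non-events; OR = ad / (bc) and
    SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d). Zero cells are an error unless
    ``continuity`` adds 0.5 to every cell (off by default).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be nonnegative")
    if np.any(cells == 0):
        if not continuity:
            raise ValueError("zero cell; enable continuity=True for a +0.5 correction")
        cells = cells + 0.5
    elif continuity:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    log_or = float(np.log(a_ * d_ / (b_ * c_)))
    se = float(np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_))
    z = norm.ppf(1.0 - alpha / 2.0)
    return ORResult(
        or_value=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        log_or=log_or,
        se_log_or=se,
        alpha=alpha,
    )


def paired_prevalence_diff_ci(
    table: TransitionTable, category: int, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Wald interval for the drop in a category's prevalence between waves.

    ``d = p_baseline - p_followup`` for the marginal proportions of
    ``category``, with the paired-proportion variance
    ``[p_row + p_col - 2 p_diag - d^2] / n`` where ``p_diag`` is the joint
    (category, category) proportion — the same children are measured twice,
    so the joint cell tightens the interval relative to independent samples.
    """
    n = table.grand_total
    if n <= 0:
        raise ValueError("grand total must be positive")
    k = int(category) - 1
    p_row = table.row_totals[k] / n
    p_col = table.col_totals[k] / n
    p_diag = table.counts[k, k] / n
    d = p_row - p_col
    var = (p_row + p_col - 2.0 * p_diag - d * d) / n
    se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(1.0 - alpha / 2.0)
    return float(d), float(d - z * se), float(d + z * se)


def logratio_profile(
    cohort: pd.DataFrame,
    numerator_cat: int = 4,
    denominator_cat: int = 2,
    age_values=tuple(range(6, 12)),
    bmi_bins=tuple(np.arange(10.0, 36.0, 2.5)),
) -> pd.DataFrame:
    """Empirical log count-ratio of two follow-up categories over an
    (age, baseline-BMI-bin) grid.

    A diagnostic for interaction structure: within a BMI bin the profile is
    roughly linear in age when the log-odds are additive. Cells where either
    category count is zero are NaN (no continuity correction). Columns are
    labelled by bin midpoints.
    """
    bmi_bins = np.asarray(bmi_bins, dtype=float)
    if len(bmi_bins) < 2:
        raise ValueError("bmi_bins must define at least one bin")
    mids = 0.5 * (bmi_bins[:-1] + bmi_bins[1:])
    y = cohort["category18"].astype("Int64")
    binned = pd.cut(cohort["bmi13"], bmi_bins, include_lowest=True)
    grid = np.full((len(age_values), len(mids)), np.nan)
    for i, age in enumerate(age_values):
        in_age = cohort["age"] == age
        for j, interval in enumerate(binned.cat.categories):
            cell = in_age & (binned == interval)
            num = int((y[cell] == numerator_cat).sum())
            den = int((y[cell] == denominator_cat).sum())
            if num > 0 and den > 0:
                grid[i, j] = np.log(num / den)
    return pd.DataFrame(grid, index=pd.Index(age_values, name="age"), columns=np.round(mids, 3))


_STRATA = ("overall", "boys", "girls", "urban", "rural")


def reference_transition_tables() -> dict[str, TransitionTable]:
    """The published 4 x 4 transition counts of the motivating cohort,
    overall and stratified by gender and district."""
    with resources.as_file(
        resources.files("bmitrans.data") / "reference_transition_counts.csv"
    ) as path:
        frame = pd.read_csv(path)
    out = {}
    for stratum in _STRATA:
        sub = frame[frame["stratum"] == stratum].sort_values("category13")
        counts = sub[["underweight18", "normal18", "overweight18", "obese18"]].to_numpy(dtype=float)
        out[stratum] = TransitionTable(counts, stratum)
    return out
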