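"""High-obesity-risk decision domains and five-year prevalence projection.

For a (gender, district, age) stratum the high-risk domain is the region of
the (height, BMI) plane where the model's predicted obesity probability
reaches a threshold (0.9 by default). Because the obesity log-odds are
increasing in BMI under the fitted transition models considered here, the
domain is bounded below by a curve: for each height on a grid, the smallest
BMI at which Pr(obese) >= threshold, found by bisection. The curve shifts
up and right with age (obesity risk declines with age at fixed size).

Prevalence projection applies the fitted one-step transition model to a new
baseline wave: per stratum the projected category rates are the mean
predicted probabilities over its children. No multi-step iteration is
attempted — the coefficients are calibrated for a single five-year
transition and may themselves drift over calendar time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParams, category_probs, probability_matrix

logger = logging.getLogger("bmitrans")

_BMI_COL = 5  # column index of bmi13 in the coefficient table


@dataclass
class RiskBoundary:
    """Minimum-BMI-versus-height curve at a fixed obesity-probability
    threshold for one (gender, district, age) stratum. ``bmi_min`` is NaN at
    heights where the threshold is unreachable within the searched range."""

    gender: int
    district: int
    age: int
    threshold: float
    heights: np.ndarray
    bmi_min: np.ndarray

    def points(self) -> list[tuple[float, float | None]]:
        return [
            (float(h), None if np.isnan(b) else float(b))
            for h, b in zip(self.heights, self.bmi_min)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"height_cm": self.heights, "bmi_min": self.bmi_min})


def obesity_probability(params: ModelParams, gender, district, age, height, bmi):
    """Pr(obese) at given covariates; vectorised over ``bmi`` (and height)."""
    bmi = np.asarray(bmi, dtype=float)
    scalar = bmi.ndim == 0
    bmi = np.atleast_1d(bmi)
    height = np.broadcast_to(np.asarray(height, dtype=float), bmi.shape)
    n = len(bmi)
    frame = pd.DataFrame(
        {
            "gender": np.full(n, gender),
            "district": np.full(n, district),
            "age": np.full(n, age),
            "height": height,
            "bmi13": bmi,
        }
    )
    p4 = probability_matrix(params, frame)[:, 3]
    return float(p4[0]) if scalar else p4


def bmi_monotone_in_obesity(params: ModelParams) -> bool:
    """Sufficient condition for Pr(obese) to be nondecreasing in BMI: the
    obese-row BMI coefficient weakly dominates every row's (including the
    baseline's zero)."""
    b = params.beta[:, _BMI_COL]
    return bool(b[2] >= max(0.0, b[0], b[1]))


def risk_boundary(
    params: ModelParams,
    gender: int,
    district: int,
    age: int,
    height_grid=None,
    bmi_range: tuple = (10.0, 35.0),
    threshold: float = 0.9,
    tol: float = 1e-6,
) -> RiskBoundary:
    """Lower BMI boundary of the high-risk domain for one stratum.

    For each grid height, bisection over ``bmi_range`` finds the smallest
    BMI with Pr(obese) >= threshold, to within ``tol`` in probability; NaN
    where even the top of the range stays below the threshold. Requires the
    monotonicity condition of :func:`bmi_monotone_in_obesity` (otherwise a
    dense grid scan of :func:`obesity_probability` must be used instead).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if not bmi_monotone_in_obesity(params):
        raise ValueError(
            "Pr(obese) is not guaranteed monotone in BMI for these coefficients; "
            "bisection is invalid — scan obesity_probability on a dense BMI grid instead"
        )
    heights = np.asarray(
        height_grid if height_grid is not None else np.arange(110.0, 171.0, 1.0),
        dtype=float,
    )
    if heights.size == 0:
        raise ValueError("height_grid must be nonempty")
    low, high = float(bmi_range[0]), float(bmi_range[1])
    if not low < high:
        raise ValueError("bmi_range: low must be strictly below high")
    bmi_min = np.full(heights.shape, np.nan)
    for i, h in enumerate(heights):
        p_low = obesity_probability(params, gender, district, age, h, low)
        p_high = obesity_probability(params, gender, district, age, h, high)
        if p_high < threshold:
            continue  # unreachable at this height
        if p_low >= threshold:
            bmi_min[i] = low
            continue
        lo, hi = low, high
        for _ in range(200):
            if p_high - p_low < tol:
                break
            mid = 0.5 * (lo + hi)
            p_mid = obesity_probability(params, gender, district, age, h, mid)
            if p_mid >= threshold:
                hi, p_high = mid, p_mid
            else:
                lo, p_low = mid, p_mid
        bmi_min[i] = hi
    return RiskBoundary(
        gender=int(gender),
        district=int(district),
        age=int(age),
        threshold=threshold,
        heights=heights,
        bmi_min=bmi_min,
    )


@dataclass
class PrevalenceProjection:
    """Current (observed baseline) versus projected (model, +5 years)
    category rates for one stratum."""

    stratum: dict
    n: int
    current_rates: np.ndarray
    projected_rates: np.ndarray


def project_prevalence(
    params: ModelParams, cohort: pd.DataFrame, strata: tuple | None = ("gender", "district")
) -> list[PrevalenceProjection]:
    """Project category prevalence one five-year step ahead, per stratum.

    ``current_rates`` are the observed baseline category shares;
    ``projected_rates`` average the model's predicted category probabilities
    over the stratum's children. Empty strata are omitted with a warning.
    """
    if len(cohort) == 0:
        logger.warning("project_prevalence: empty cohort, nothing to project")
        return []
    probs = probability_matrix(params, cohort)
    cat13 = cohort["category13"].to_numpy(dtype=int)

    def _one(mask: np.ndarray, label: dict) -> PrevalenceProjection:
        current = np.array([(cat13[mask] == c).mean() for c in (1, 2, 3, 4)])
        return PrevalenceProjection(
            stratum=label,
            n=int(mask.sum()),
            current_rates=current,
            projected_rates=probs[mask].mean(axis=0),
        )

    if not strata:
        return [_one(np.ones(len(cohort), dtype=bool), {})]
    out = []
    for levels, group in cohort.groupby(list(strata), sort=True):
        if not isinstance(levels, tuple):
            levels = (levels,)
        mask = cohort.index.isin(group.index)
        out.append(_one(mask, dict(zip(strata, levels))))
    return out
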