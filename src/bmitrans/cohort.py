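"""Synthetic two-wave cohort generation.

A cohort is a :class:`pandas.DataFrame` with one row per child and columns

``id, gender, district, age, height, bmi13, category13, category18``

where ``gender`` (1 = male) and ``district`` (1 = urban) are binary, ``age``
is integer years at baseline (6-11), ``height`` is baseline height in cm,
``bmi13`` baseline BMI in kg/m^2, and the categories are the 1-4 nutrition
codes. ``category18`` is the five-year follow-up category (nullable until
:func:`generate_followup` fills it).

The generator emulates the covariate margins of a large two-wave school
cohort (~51% boys, ~56% urban, ages 6-11 with mass concentrated at 7-9) and
samples follow-up categories from the baseline-category logit model in
:mod:`bmitrans.model`; by default the truth is the packaged reference
coefficient set, so the generated data exercise exactly the transition
structure the downstream analyses estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
import json

import numpy as np
import pandas as pd
import yaml

from .categories import AGES, CutoffTable, classify_bmi

logger = logging.getLogger("bmitrans")

COHORT_COLUMNS = [
    "id", "gender", "district", "age", "height", "bmi13", "category13", "category18",
]
COVARIATE_COLUMNS = ["gender", "district", "age", "height", "bmi13"]


def _reference_margins() -> dict:
    text = (resources.files("bmitrans.data") / "reference_baseline_margins.json").read_text()
    return json.loads(text)


_M = _reference_margins()
#: Default categorical margins: exact baseline proportions of the motivating cohort.
DEFAULT_P_MALE = _M["boys"] / _M["total"]
DEFAULT_P_URBAN = _M["urban"] / _M["total"]
DEFAULT_AGE_PROBS = tuple(_M["age_counts"][str(a)] / _M["total"] for a in AGES)


@dataclass(frozen=True)
class GrowthModel:
    """Gender-specific linear-in-age normal model for a body measurement."""

    intercept_female: float
    intercept_male: float
    age_slope: float
    sd: float

    def mean(self, gender, age):
        gender = np.asarray(gender, dtype=float)
        age = np.asarray(age, dtype=float)
        return (
            self.intercept_female
            + (self.intercept_male - self.intercept_female) * gender
            + self.age_slope * age
        )


#: Default anthropometry: height ~ N(100 + 6*age + 2*gender, 7) cm and
#: bmi13 ~ N(14.5 + 0.45*age + 0.5*gender, 2.5) kg/m^2 truncated to bmi_range.
DEFAULT_HEIGHT_MODEL = GrowthModel(100.0, 102.0, 6.0, 7.0)
DEFAULT_BMI_MODEL = GrowthModel(14.5, 15.0, 0.45, 2.5)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator."""

    n: int
    p_male: float = DEFAULT_P_MALE
    p_urban: float = DEFAULT_P_URBAN
    age_probs: tuple = DEFAULT_AGE_PROBS
    height_model: GrowthModel = DEFAULT_HEIGHT_MODEL
    bmi_model: GrowthModel = DEFAULT_BMI_MODEL
    bmi_range: tuple = (10.0, 35.0)
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n < 0:
            raise ValueError("n: must be a nonnegative integer")
        for name in ("p_male", "p_urban"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}: probability must be in [0, 1]")
        probs = np.asarray(self.age_probs, dtype=float)
        if probs.shape != (len(AGES),):
            raise ValueError(f"age_probs: expected {len(AGES)} probabilities")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("age_probs: probabilities must be in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("age_probs: must sum to 1")
        for name in ("height_model", "bmi_model"):
            if getattr(self, name).sd <= 0:
                raise ValueError(f"{name}: standard deviation must be positive")
        low, high = self.bmi_range
        if not low < high:
            raise ValueError("bmi_range: low must be strictly below high")

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        """Load a config from YAML or JSON mirroring the field names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("height_model", "bmi_model"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = GrowthModel(**raw[key])
        if "age_probs" in raw:
            raw["age_probs"] = tuple(raw["age_probs"])
        if "bmi_range" in raw:
            raw["bmi_range"] = tuple(raw["bmi_range"])
        return cls(**raw)


def _truncated_normal(rng, mean, sd, low, high, max_attempts=1000):
    """Rejection-sample N(mean, sd) into [low, high] (no boundary atoms)."""
    draw = rng.normal(mean, sd)
    out_of_range = (draw < low) | (draw > high)
    attempts = 1
    while np.any(out_of_range):
        if attempts >= max_attempts:
            raise RuntimeError(
                f"truncated-normal rejection sampling failed after {max_attempts} "
                "attempts; bmi_range is likely far from the bmi_model mass"
            )
        redraw = rng.normal(np.asarray(mean)[out_of_range], sd)
        draw[out_of_range] = redraw
        out_of_range = (draw < low) | (draw > high)
        attempts += 1
    return draw


def generate_baseline(config: CohortConfig, cutoffs: CutoffTable | None = None) -> pd.DataFrame:
    """Draw a baseline wave: covariates plus ``category13`` (no follow-up yet).

    Gender, district and age are independent draws from the configured
    margins; height and BMI follow the gender/age growth models, with BMI
    rejection-sampled into ``bmi_range``. ``category13`` is assigned from the
    active cutoff table. Fixed ``(config, seed)`` gives identical output.
    """
    config.validate()
    cutoffs = cutoffs or CutoffTable.default()
    rng = np.random.default_rng(config.seed)
    n = int(config.n)
    if n == 0:
        frame = pd.DataFrame({c: [] for c in COHORT_COLUMNS})
        return frame.astype({"category18": "Int64"}, errors="ignore")

    gender = (rng.random(n) < config.p_male).astype(int)
    district = (rng.random(n) < config.p_urban).astype(int)
    age = rng.choice(np.asarray(AGES), size=n, p=np.asarray(config.age_probs, dtype=float))
    height = rng.normal(config.height_model.mean(gender, age), config.height_model.sd)
    low, high = config.bmi_range
    bmi13 = _truncated_normal(rng, config.bmi_model.mean(gender, age), config.bmi_model.sd, low, high)
    category13 = classify_bmi(bmi13, age, gender, cutoffs)
    frame = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "gender": gender,
            "district": district,
            "age": age.astype(int),
            "height": height,
            "bmi13": bmi13,
            "category13": category13,
            "category18": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )
    return frame


def generate_followup(cohort: pd.DataFrame, params, seed: int) -> pd.DataFrame:
    """Sample ``category18`` for every child from the transition model.

    For each record the follow-up category is a single draw from the
    four-category distribution of the baseline-category logit model at
    ``x = (gender, district, age, height, bmi13)``. Returns a copy.
    """
    from .model import probability_matrix  # local import to avoid a cycle

    missing = cohort[COVARIATE_COLUMNS].isna().any(axis=1)
    if missing.any():
        bad_ids = cohort.loc[missing, "id"].tolist()
        raise ValueError(f"records with missing covariates: ids {bad_ids[:20]}")
    out = cohort.copy()
    if len(out) == 0:
        return out
    probs = probability_matrix(params, out)
    rng = np.random.default_rng(seed)
    u = rng.random(len(out))
    cum = np.cumsum(probs, axis=1)
    cats = 1 + (u[:, None] > cum[:, :3]).sum(axis=1)
    out["category18"] = pd.array(cats, dtype="Int64")
    return out


def generate_cohort(config: CohortConfig, params=None, cutoffs: CutoffTable | None = None) -> pd.DataFrame:
    """Baseline plus follow-up in one call (default truth: packaged reference
    coefficients). The follow-up stream is seeded from ``config.seed``."""
    from .model import ModelParams

    params = params if params is not None else ModelParams.reference_smle()
    baseline = generate_baseline(config, cutoffs=cutoffs)
    return generate_followup(baseline, params, seed=int(config.seed) + 1_000_003)


def filter_bmi_range(cohort: pd.DataFrame, low: float = 10.0, high: float = 35.0) -> pd.DataFrame:
    """Keep records with ``low <= bmi13 <= high``; logs the removed count."""
    if not low < high:
        raise ValueError("bmi_range: low must be strictly below high")
    keep = (cohort["bmi13"] >= low) & (cohort["bmi13"] <= high)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_bmi_range: removed %d of %d records", removed, len(cohort))
    return cohort.loc[keep].reset_index(drop=True)
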