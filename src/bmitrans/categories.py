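"""BMI computation and four-category nutrition-status classification.

Nutrition categories are coded the same way everywhere in the package:
``1`` underweight, ``2`` normal, ``3`` overweight, ``4`` obese. A child is
classified from BMI through an age- and gender-specific :class:`CutoffTable`
(Chinese school-age screening standards use separate thresholds per gender
and age group). Thresholds are inclusive for the heavier category, i.e.
``bmi == obese_min`` is obese.

The packaged default table (``data/synthetic_cutoffs.csv``) is synthetic and
non-normative: it exists so the pipeline runs end to end with all four
categories populated. Real analyses must supply the applicable national
cutoff table via :meth:`CutoffTable.from_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

CATEGORY_LABELS = {1: "underweight", 2: "normal", 3: "overweight", 4: "obese"}
GENDERS = (0, 1)  # 0 = female, 1 = male
AGES = (6, 7, 8, 9, 10, 11)  # integer years at baseline

_CUTOFF_COLUMNS = ["underweight_max", "overweight_min", "obese_min"]


def compute_bmi(weight_kg, height_cm):
    """Body mass index, weight (kg) / height (m)^2.

    Accepts scalars or arrays; heights are in centimetres. Raises
    ``ValueError`` on any non-positive weight or height.
    """
    weight = np.asarray(weight_kg, dtype=float)
    height = np.asarray(height_cm, dtype=float)
    if np.any(weight <= 0):
        raise ValueError("weight_kg must be positive")
    if np.any(height <= 0):
        raise ValueError("height_cm must be positive")
    bmi = weight / (height / 100.0) ** 2
    return float(bmi) if bmi.ndim == 0 else bmi


@dataclass(frozen=True)
class CutoffTable:
    """Age/gender-specific BMI thresholds for the four nutrition categories.

    ``frame`` is indexed by ``(gender, age)`` with columns
    ``underweight_max``, ``overweight_min``, ``obese_min`` (kg/m^2), strictly
    increasing within each row, and must cover all 12 (gender, age) keys.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.frame
        missing_cols = [c for c in _CUTOFF_COLUMNS if c not in frame.columns]
        if missing_cols:
            raise ValueError(f"cutoff table missing columns: {missing_cols}")
        expected = {(g, a) for g in GENDERS for a in AGES}
        present = set(map(tuple, frame.index))
        missing = sorted(expected - present)
        if missing:
            raise ValueError(f"cutoff table missing (gender, age) keys: {missing}")
        bad = frame[
            ~(
                (frame["underweight_max"] < frame["overweight_min"])
                & (frame["overweight_min"] < frame["obese_min"])
            )
        ]
        if len(bad):
            raise ValueError(
                "cutoffs must satisfy underweight_max < overweight_min < obese_min; "
                f"violated at keys {list(bad.index)}"
            )

    @classmethod
    def from_csv(cls, path) -> "CutoffTable":
        frame = pd.read_csv(path)
        required = ["gender", "age", *_CUTOFF_COLUMNS]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"cutoff CSV missing columns: {missing}")
        frame = frame.set_index(["gender", "age"])[_CUTOFF_COLUMNS].astype(float)
        return cls(frame)

    @classmethod
    def default(cls) -> "CutoffTable":
        """The packaged synthetic (non-normative) cutoff table."""
        with resources.as_file(
            resources.files("bmitrans.data") / "synthetic_cutoffs.csv"
        ) as path:
            return cls.from_csv(path)

    def to_csv(self, path) -> None:
        self.frame.reset_index().to_csv(path, index=False)

    def lookup(self, gender: int, age: int) -> tuple[float, float, float]:
        """Return ``(underweight_max, overweight_min, obese_min)`` for a key."""
        try:
            row = self.frame.loc[(int(gender), int(age))]
        except KeyError:
            raise KeyError(f"no cutoffs for (gender={gender}, age={age})") from None
        return tuple(float(row[c]) for c in _CUTOFF_COLUMNS)

    def threshold_arrays(self, gender, age) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised lookup: three arrays aligned with ``gender``/``age``."""
        idx = pd.MultiIndex.from_arrays(
            [np.asarray(gender, dtype=int), np.asarray(age, dtype=int)]
        )
        sub = self.frame.reindex(idx)
        if sub[_CUTOFF_COLUMNS[0]].isna().any():
            bad = sorted(set(idx[sub[_CUTOFF_COLUMNS[0]].isna()]))
            raise KeyError(f"no cutoffs for (gender, age) keys: {bad}")
        return tuple(sub[c].to_numpy(dtype=float) for c in _CUTOFF_COLUMNS)


def classify_bmi(bmi, age, gender, cutoffs: CutoffTable | None = None):
    """Map BMI to category 1-4 under the age/gender-specific thresholds.

    Boundary convention: thresholds belong to the heavier category
    (``bmi == overweight_min`` is overweight, ``bmi == obese_min`` is obese;
    underweight requires ``bmi < underweight_max``). Accepts scalars or
    aligned arrays.
    """
    cutoffs = cutoffs or CutoffTable.default()
    bmi_arr = np.atleast_1d(np.asarray(bmi, dtype=float))
    scalar = np.ndim(bmi) == 0
    uw, ow, ob = cutoffs.threshold_arrays(
        np.broadcast_to(np.atleast_1d(gender), bmi_arr.shape),
        np.broadcast_to(np.atleast_1d(age), bmi_arr.shape),
    )
    cat = np.full(bmi_arr.shape, 2, dtype=int)
    cat[bmi_arr < uw] = 1
    cat[bmi_arr >= ow] = 3
    cat[bmi_arr >= ob] = 4
    return int(cat[0]) if scalar else cat
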