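"""Cohort CSV input/output and pipeline configuration.

On disk a cohort is a comma-separated UTF-8 file with header

    id,gender,district,age,height_cm,weight_kg,bmi13,category13,category18

``weight_kg`` is optional when ``bmi13`` is present (and vice versa — BMI is
derived from weight and height when absent); ``category18`` is empty for
baseline-only records. In memory the height column is ``height`` (cm) and
``category18`` is a nullable integer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .categories import CutoffTable, compute_bmi

logger = logging.getLogger("bmitrans")

_REQUIRED = ["id", "gender", "district", "age", "height_cm"]
_NUMERIC = ["gender", "district", "age", "height_cm", "weight_kg", "bmi13", "category13", "category18"]


def read_cohort(path, cutoffs: CutoffTable | None = None) -> pd.DataFrame:
    """Read a cohort CSV into the in-memory frame.

    Missing required columns raise; unparseable values raise with the row
    number; rows with missing required fields are dropped with a logged
    count. ``bmi13`` is computed from ``weight_kg`` when absent, and
    ``category13`` from the cutoff table when absent.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in _REQUIRED if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"cohort CSV missing required columns: {missing_cols}")
    if "bmi13" not in frame.columns and "weight_kg" not in frame.columns:
        raise ValueError("cohort CSV needs either a bmi13 or a weight_kg column")
    for col in frame.columns:
        if col not in _NUMERIC and col != "id":
            continue
        blank = frame[col].str.strip() == ""
        parsed = pd.to_numeric(frame[col].where(~blank), errors="coerce")
        bad = parsed.isna() & ~blank
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"unparseable value in column {col!r} at line {row}")
        frame[col] = parsed

    required_fields = [c for c in (_REQUIRED + ["bmi13"]) if c in frame.columns]
    if "bmi13" not in frame.columns:
        required_fields.append("weight_kg")
    complete = frame[required_fields].notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("read_cohort: dropped %d incomplete rows of %d", dropped, len(frame))
    frame = frame.loc[complete].reset_index(drop=True)
    if len(frame) == 0:
        logger.warning("read_cohort: no complete records in %s", path)

    out = pd.DataFrame(
        {
            "id": frame["id"].astype(int) if len(frame) else pd.Series([], dtype=int),
            "gender": frame["gender"].astype(int) if len(frame) else pd.Series([], dtype=int),
            "district": frame["district"].astype(int) if len(frame) else pd.Series([], dtype=int),
            "age": frame["age"].astype(int) if len(frame) else pd.Series([], dtype=int),
            "height": frame["height_cm"].astype(float) if len(frame) else pd.Series([], dtype=float),
        }
    )
    if "bmi13" in frame.columns and frame["bmi13"].notna().all() and len(frame):
        out["bmi13"] = frame["bmi13"].astype(float)
    elif len(frame):
        out["bmi13"] = compute_bmi(frame["weight_kg"].to_numpy(float), out["height"].to_numpy())
    else:
        out["bmi13"] = pd.Series([], dtype=float)
    if "category13" in frame.columns and len(frame) and frame["category13"].notna().all():
        out["category13"] = frame["category13"].astype(int)
    elif len(frame):
        from .categories import classify_bmi

        out["category13"] = classify_bmi(
            out["bmi13"].to_numpy(), out["age"].to_numpy(), out["gender"].to_numpy(),
            cutoffs or CutoffTable.default(),
        )
    else:
        out["category13"] = pd.Series([], dtype=int)
    if "category18" in frame.columns:
        out["category18"] = frame["category18"].round().astype("Int64")
    else:
        out["category18"] = pd.array([pd.NA] * len(out), dtype="Int64")
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort frame to CSV (``category18`` empty when absent)."""
    out = cohort.copy()
    out = out.rename(columns={"height": "height_cm"})
    cols = ["id", "gender", "district", "age", "height_cm", "bmi13", "category13", "category18"]
    out[cols].to_csv(path, index=False, float_format="%.6f", na_rep="")


@dataclass
class PipelineConfig:
    """Bundled settings for an end-to-end run (paths plus analysis knobs)."""

    cohort_path: str | None = None
    cutoffs_path: str | None = None
    params_path: str | None = None
    alpha: float = 0.05
    cv_k: int = 5
    cv_repeats: int = 100
    seed: int = 0
    risk_threshold: float = 0.9
    bmi_range: tuple = (10.0, 35.0)
    fit_method: str = "smle"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.risk_threshold < 1.0:
            raise ValueError("risk_threshold must be in (0, 1)")
        if self.fit_method.lower() not in ("smle", "gmle"):
            raise ValueError("fit_method must be 'smle' or 'gmle'")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "bmi_range" in raw:
            raw["bmi_range"] = tuple(raw["bmi_range"])
        return cls(**raw)


def write_json(payload: dict, path) -> None:
    """Write a JSON artifact (numpy types coerced to plain Python)."""

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
        fh.write("\n")
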