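"""Classical adult-height predictors used as comparison baselines.

Two textbook methods:

* mid-parental ("genetic height") linear formulas, one per sex, mapping
  parent heights straight to a predicted adult height;
* the Bayley-Pinneau percentage method, ``Y = H / FP``, where FP is the
  fraction of adult height already attained at the child's current bone
  age, looked up in a per-sex, per-developmental-category table.

Developmental category (early / normal / late maturer) is an input here,
not something the package infers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import _check_sex

__all__ = [
    "FpTable",
    "genetic_height",
    "bayley_pinneau",
    "lookup_fp",
    "load_fp_table",
]

CATEGORIES = ("early", "normal", "late")
PARENT_HEIGHT_RANGE = (100.0, 230.0)

# Per-sex mid-parental regression coefficients: (intercept, father, mother).
_GENETIC_COEF = {
    "M": (56.699, 0.419, 0.265),
    "F": (40.089, 0.306, 0.431),
}


def genetic_height(sex: str, father_height: float, mother_height: float) -> float:
    """Mid-parental adult-height prediction (cm).

    Boys: 56.699 + 0.419*father + 0.265*mother;
    girls: 40.089 + 0.306*father + 0.431*mother.
    """
    _check_sex(sex)
    lo, hi = PARENT_HEIGHT_RANGE
    for name, v in (("father_height", father_height),
                    ("mother_height", mother_height)):
        if not lo < v < hi:
            raise ValueError(f"{name}={v} outside ({lo}, {hi})")
    c0, cf, cm = _GENETIC_COEF[sex]
    return c0 + cf * father_height + cm * mother_height


def bayley_pinneau(current_height: float, fp: float) -> float:
    """Adult height as current height divided by the attained fraction FP."""
    if not 0.0 < fp <= 1.0:
        raise ValueError(f"fp must lie in (0, 1], got {fp}")
    if current_height <= 0:
        raise ValueError("current_height must be positive")
    return current_height / fp


@dataclass(frozen=True)
class FpTable:
    """Fraction-of-adult-height attained vs. bone age.

    FP values are stored as fractions in (0, 1]; tables published as
    percentages are divided by 100 at load time.
    """

    sex: str
    developmental_category: str
    bone_ages: np.ndarray
    fp_values: np.ndarray

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        if self.developmental_category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")
        ba = np.asarray(self.bone_ages, dtype=float)
        fp = np.asarray(self.fp_values, dtype=float)
        object.__setattr__(self, "bone_ages", ba)
        object.__setattr__(self, "fp_values", fp)
        if ba.ndim != 1 or ba.size != fp.size or ba.size < 2:
            raise ValueError("bone_ages and fp_values must be 1-D, equal, >=2")
        if np.any(np.diff(ba) <= 0):
            raise ValueError("bone ages must be strictly increasing")
        if np.any(fp <= 0) or np.any(fp > 1):
            raise ValueError("FP values must lie in (0, 1]")
        if np.any(np.diff(fp) < 0):
            raise ValueError("FP must be non-decreasing in bone age")


def lookup_fp(table: FpTable, bone_age: float) -> float:
    """Linearly interpolate FP at a bone age inside the table range."""
    ba = table.bone_ages
    if not ba[0] <= bone_age <= ba[-1]:
        raise ValueError(
            f"bone age {bone_age} outside table range [{ba[0]}, {ba[-1]}]")
    return float(np.interp(bone_age, ba, table.fp_values))


def load_fp_table(path: str | Path, sex: str,
                  category: str = "normal") -> FpTable:
    """Read an FP CSV with columns ``sex,category,bone_age,fp``.

    An optional ``fp_is_percent`` column (0/1) flags rows published as
    percentages, which are divided by 100.
    """
    _check_sex(sex)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FP table not found: {path}")
    df = pd.read_csv(path)
    missing = {"sex", "category", "bone_age", "fp"} - set(df.columns)
    if missing:
        raise ValueError(f"FP CSV lacks columns {sorted(missing)}")
    df = df[(df["sex"] == sex) & (df["category"] == category)]
    if df.empty:
        raise ValueError(f"no FP rows for sex {sex!r}, category {category!r}")
    df = df.sort_values("bone_age")
    fp = df["fp"].to_numpy(float)
    if "fp_is_percent" in df.columns:
        pct = df["fp_is_percent"].to_numpy(bool)
        fp = np.where(pct, fp / 100.0, fp)
    return FpTable(sex=sex, developmental_category=category,
                   bone_ages=df["bone_age"].to_numpy(float), fp_values=fp)
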