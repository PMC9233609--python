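"""Measurement records and the six-dimensional model input.

Each clinic visit yields bone age, chronological age, height and weight.
The regression input appends two derived channels: BMI and the deviation of
that BMI from a standard BMI-for-age reference (``delta_bmi``).  Adiposity
advances skeletal maturation, so the BMI channels let the adult-height
model separate a tall-because-early child from a tall-because-tall one.

Sex is deliberately not a feature: separate male and female models are
trained, and every model in the package is keyed by sex.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .reference import VALID_SEXES, _check_sex

__all__ = [
    "FEATURE_NAMES",
    "SubjectRecord",
    "StandardBmiTable",
    "FeatureVector",
    "FeatureBuilder",
    "compute_bmi",
    "compute_delta_bmi",
    "build_features",
    "load_standard_bmi_table",
    "load_cohort",
]

#: Input-feature order used everywhere (columns of the n x 6 design matrix).
FEATURE_NAMES = ("bone_age", "age", "height", "weight", "bmi", "delta_bmi")

AGE_RANGE = (0.0, 25.0)
BONE_AGE_RANGE = (0.0, 20.0)
HEIGHT_RANGE = (40.0, 230.0)
WEIGHT_RANGE = (2.0, 200.0)


@dataclass(frozen=True)
class SubjectRecord:
    """One growth measurement for one child."""

    subject_id: str
    sex: str
    age: float
    bone_age: float
    height: float
    weight: float
    adult_height: float | None = None
    measured_on: str | None = None

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        for name, value, (lo, hi) in (
            ("age", self.age, AGE_RANGE),
            ("bone_age", self.bone_age, BONE_AGE_RANGE),
            ("height", self.height, HEIGHT_RANGE),
            ("weight", self.weight, WEIGHT_RANGE),
        ):
            if value is None or not np.isfinite(value) or not lo < value <= hi:
                raise ValueError(f"{name}={value!r} outside ({lo}, {hi}]")


@dataclass(frozen=True)
class StandardBmiTable:
    """Per-sex standard (reference median) BMI-for-age grid, kg/m^2."""

    sex: str
    ages: np.ndarray
    bmi_values: np.ndarray

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        ages = np.asarray(self.ages, dtype=float)
        bmi = np.asarray(self.bmi_values, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "bmi_values", bmi)
        if ages.ndim != 1 or ages.size != bmi.size or ages.size < 2:
            raise ValueError("ages and bmi_values must be 1-D, equal length, >=2")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(bmi <= 0):
            raise ValueError("standard BMI values must be positive")

    def standard_bmi(self, age: float) -> float:
        """Linearly interpolated standard BMI at ``age`` (errors outside grid)."""
        if not self.ages[0] <= age <= self.ages[-1]:
            raise ValueError(
                f"age {age} outside standard-BMI table range "
                f"[{self.ages[0]}, {self.ages[-1]}]")
        return float(np.interp(age, self.ages, self.bmi_values))


@dataclass(frozen=True)
class FeatureVector:
    """The six model inputs, in fixed order (see :data:`FEATURE_NAMES`)."""

    bone_age: float
    age: float
    height: float
    weight: float
    bmi: float
    delta_bmi: float

    def as_array(self) -> np.ndarray:
        return np.array([self.bone_age, self.age, self.height,
                         self.weight, self.bmi, self.delta_bmi], dtype=float)


def compute_bmi(weight: float, height: float) -> float:
    """BMI = W / H^2 with weight in kg and height given in cm.

    Height is converted to meters internally; everywhere else in the
    package heights stay in cm.
    """
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return weight / (height / 100.0) ** 2


def compute_delta_bmi(bmi: float, age: float, table: StandardBmiTable) -> float:
    """Subject BMI minus the standard BMI-for-age at the same age."""
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    return bmi - table.standard_bmi(age)


def build_features(record: SubjectRecord, table: StandardBmiTable) -> FeatureVector:
    """Encode one measurement as the six-feature input vector.

    BMI is always recomputed from the record's weight and height rather
    than taken on trust from any input column.
    """
    bmi = compute_bmi(record.weight, record.height)
    delta = compute_delta_bmi(bmi, record.age, table)
    return FeatureVector(bone_age=record.bone_age, age=record.age,
                         height=record.height, weight=record.weight,
                         bmi=bmi, delta_bmi=delta)


class FeatureBuilder(BaseEstimator, TransformerMixin):
    """Transformer mapping a cohort DataFrame to the n x 6 feature matrix.

    Stateless apart from its ``bmi_table`` parameter; ``fit`` is a no-op so
    the builder slots into sklearn pipelines.
    """

    def __init__(self, bmi_table: StandardBmiTable | None = None):
        self.bmi_table = bmi_table

    def fit(self, X=None, y=None) -> "FeatureBuilder":
        if self.bmi_table is None:
            raise ValueError("FeatureBuilder requires a bmi_table")
        return self

    def transform(self, cohort: pd.DataFrame) -> np.ndarray:
        if self.bmi_table is None:
            raise ValueError("FeatureBuilder requires a bmi_table")
        rows = []
        for rec in iter_records(cohort):
            rows.append(build_features(rec, self.bmi_table).as_array())
        if not rows:
            raise ValueError("empty cohort")
        return np.vstack(rows)


def load_standard_bmi_table(path: str | Path, sex: str) -> StandardBmiTable:
    """Read a standard-BMI CSV with columns ``sex,age,bmi`` for one sex."""
    _check_sex(sex)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"standard-BMI table not found: {path}")
    df = pd.read_csv(path)
    missing = {"sex", "age", "bmi"} - set(df.columns)
    if missing:
        raise ValueError(f"standard-BMI CSV lacks columns {sorted(missing)}")
    df = df[df["sex"] == sex].sort_values("age")
    if df.empty:
        raise ValueError(f"no rows for sex {sex!r} in {path}")
    return StandardBmiTable(sex=sex, ages=df["age"].to_numpy(float),
                            bmi_values=df["bmi"].to_numpy(float))


COHORT_COLUMNS = ("subject_id", "sex", "age", "bone_age", "height", "weight")


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV (one row per measurement) and validate its schema.

    Required columns: ``subject_id,sex,age,bone_age,height,weight``;
    optional: ``adult_height,measured_on``.  Sex is encoded M/F.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks columns {sorted(missing)}")
    bad_sex = set(df["sex"].unique()) - set(VALID_SEXES)
    if bad_sex:
        raise ValueError(f"cohort has invalid sex codes {sorted(bad_sex)}")
    if df[list(COHORT_COLUMNS)].isna().any().any():
        raise ValueError("cohort CSV contains missing required cells")
    return df


def iter_records(cohort: pd.DataFrame):
    """Yield :class:`SubjectRecord` objects from a cohort DataFrame."""
    for row in cohort.itertuples(index=False):
        adult = getattr(row, "adult_height", None)
        if adult is not None and not np.isfinite(adult):
            adult = None
        yield SubjectRecord(
            subject_id=str(row.subject_id), sex=row.sex,
            age=float(row.age), bone_age=float(row.bone_age),
            height=float(row.height), weight=float(row.weight),
            adult_height=None if adult is None else float(adult),
            measured_on=getattr(row, "measured_on", None))
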