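"""Population mean growth curve.

A national growth reference supplies, per sex, the mean (0 SD) height at a
grid of ages.  This module loads such a table and fits a polynomial
height-for-age curve ``f(x)`` to it by least squares.  The fitted curve is
the backbone of the whole package: the per-child registration in
:mod:`staturekit.personal` warps exactly this curve.

Numerically the fit is performed on ages mapped to ``[-1, 1]`` (a raw
Vandermonde matrix on ages 0-18 at degree 5 has a condition number above
1e9) and the coefficients are converted back to the ordinary power basis
afterwards.  A textbook normal-equation solver is also provided
(:func:`normal_equation_fit`) so the production path can be cross-checked
against the closed form ``A = (X^T X)^{-1} X^T y``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ReferenceTable",
    "MeanGrowthCurve",
    "LeastSquaresFit",
    "load_reference_table",
    "fit_polynomial",
    "eval_curve",
    "normal_equation_fit",
]

VALID_SEXES = ("M", "F")


def _check_sex(sex: str) -> str:
    if sex not in VALID_SEXES:
        raise ValueError(f"sex must be one of {VALID_SEXES}, got {sex!r}")
    return sex


@dataclass(frozen=True)
class ReferenceTable:
    """Per-sex grid of (age, mean height) pairs from a growth reference.

    Ages are in years and must be strictly increasing; heights are the mean
    (0 SD column) stature in cm and must be positive and non-decreasing.
    """

    sex: str
    ages: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        ages = np.asarray(self.ages, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "heights", heights)
        if ages.ndim != 1 or heights.ndim != 1 or ages.size != heights.size:
            raise ValueError("ages and heights must be 1-D and equal length")
        if ages.size < 2:
            raise ValueError("reference table needs at least 2 rows")
        if not np.all(np.isfinite(ages)) or not np.all(np.isfinite(heights)):
            raise ValueError("reference table contains non-finite values")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing (no duplicates)")
        if np.any(heights <= 0):
            raise ValueError("heights must be positive")
        if np.any(np.diff(heights) < 0):
            raise ValueError("mean heights must be non-decreasing with age")

    def __len__(self) -> int:
        return int(self.ages.size)


def load_reference_table(path: str | Path, sex: str) -> ReferenceTable:
    """Read a reference CSV with columns ``age,height`` (cm) for one sex.

    Rows are sorted by age; duplicate ages, missing cells and files with
    fewer than two rows are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reference table not found: {path}")
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed reference CSV {path}: {exc}") from exc
    missing = {"age", "height"} - set(df.columns)
    if missing:
        raise ValueError(f"reference CSV {path} lacks columns {sorted(missing)}")
    if df[["age", "height"]].isna().any().any():
        raise ValueError(f"reference CSV {path} contains missing cells")
    df = df.sort_values("age")
    return ReferenceTable(sex=sex, ages=df["age"].to_numpy(float),
                          heights=df["height"].to_numpy(float))


@dataclass
class LeastSquaresFit:
    """Explicit normal-equation least-squares fit (cross-check object).

    ``design`` is the k x (n+1) matrix of age powers (highest power first),
    ``solution`` the coefficient vector A solving
    ``A = (X^T X)^{-1} X^T y`` and ``sse`` the sum of squared residuals in
    cm^2.
    """

    design: np.ndarray
    targets: np.ndarray
    solution: np.ndarray
    sse: float


def normal_equation_fit(ages, heights, degree: int) -> LeastSquaresFit:
    """Solve the polynomial least-squares problem via the normal equations.

    Kept as the closed-form reference route; :class:`MeanGrowthCurve` uses a
    scaled, orthogonalised solve instead, which is much better conditioned.
    """
    ages = np.asarray(ages, dtype=float)
    heights = np.asarray(heights, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if np.unique(ages).size < degree + 1:
        raise ValueError("need at least degree+1 distinct ages")
    X = np.vander(ages, degree + 1)  # columns x^n ... x^0
    gram = X.T @ X
    solution = np.linalg.solve(gram, X.T @ heights)
    resid = X @ solution - heights
    return LeastSquaresFit(design=X, targets=heights, solution=solution,
                           sse=float(resid @ resid))


class MeanGrowthCurve(BaseEstimator, RegressorMixin):
    """Polynomial mean height-for-age curve ``f(x)``.

    Parameters
    ----------
    degree : int, default 5
        Polynomial degree n >= 1.  Degrees 4-6 reproduce the smooth
        sigmoid-like shape of national mean-height curves on typical grids.
    sex : {"M", "F"}, default "M"
        Which population the curve describes; purely a label, the fit does
        not use it.

    Fitted attributes
    -----------------
    coefficients_ : ndarray, shape (degree+1,)
        Power-basis coefficients, highest power first (``[a_n ... a_1, a_0]``).
    age_min_, age_max_ : float
        Fit domain in years.  ``predict`` clamps ages above ``age_max_``
        (heights plateau at adulthood) and raises below ``age_min_``.
    fit_rmse_ : float
        Root-mean-square residual of the fit, cm.
    sse_ : float
        Sum of squared residuals, cm^2.
    """

    def __init__(self, degree: int = 5, sex: str = "M"):
        self.degree = degree
        self.sex = sex

    def fit(self, ages, heights=None) -> "MeanGrowthCurve":
        """Fit the polynomial to (age, height) pairs.

        ``ages`` may also be a :class:`ReferenceTable`, in which case
        ``heights`` is ignored.
        """
        if isinstance(ages, ReferenceTable):
            table = ages
            ages, heights = table.ages, table.heights
        _check_sex(self.sex)
        ages = np.asarray(ages, dtype=float).ravel()
        heights = np.asarray(heights, dtype=float).ravel()
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if ages.size != heights.size or ages.size == 0:
            raise ValueError("ages and heights must be equal-length and non-empty")
        if np.unique(ages).size < self.degree + 1:
            raise ValueError(
                f"degree-{self.degree} fit needs at least {self.degree + 1} "
                f"distinct ages, got {np.unique(ages).size}")
        # Fit on the scaled domain, then convert back to the power basis.
        poly = np.polynomial.Polynomial.fit(ages, heights, self.degree)
        self.coefficients_ = poly.convert().coef[::-1].copy()
        self.age_min_ = float(ages.min())
        self.age_max_ = float(ages.max())
        resid = np.polyval(self.coefficients_, ages) - heights
        self.sse_ = float(resid @ resid)
        self.fit_rmse_ = float(np.sqrt(self.sse_ / ages.size))
        return self

    def predict(self, ages):
        """Evaluate the curve (Horner scheme) at ages in years.

        Ages above ``age_max_`` are clamped to ``age_max_``; ages below
        ``age_min_`` raise rather than extrapolate.
        """
        check_is_fitted(self, "coefficients_")
        arr = np.asarray(ages, dtype=float)
        scalar = arr.ndim == 0
        arr = np.atleast_1d(arr).ravel()
        if not np.all(np.isfinite(arr)):
            raise ValueError("ages must be finite")
        if np.any(arr < self.age_min_):
            raise ValueError(
                f"age below fit domain [{self.age_min_}, {self.age_max_}]")
        out = np.polyval(self.coefficients_, np.minimum(arr, self.age_max_))
        return float(out[0]) if scalar else out

    def __call__(self, age: float) -> float:
        return self.predict(age)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "coefficients_")
        return {
            "sex": self.sex,
            "degree": int(self.degree),
            "coefficients": [float(c) for c in self.coefficients_],
            "age_min": self.age_min_,
            "age_max": self.age_max_,
            "fit_rmse": self.fit_rmse_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeanGrowthCurve":
        curve = cls(degree=int(d["degree"]), sex=d["sex"])
        coef = np.asarray(d["coefficients"], dtype=float)
        if coef.size != curve.degree + 1:
            raise ValueError("coefficient count does not match degree")
        curve.coefficients_ = coef
        curve.age_min_ = float(d["age_min"])
        curve.age_max_ = float(d["age_max"])
        curve.fit_rmse_ = float(d["fit_rmse"])
        curve.sse_ = float(d["fit_rmse"]) ** 2  # per-point scale unknown
        return curve

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "MeanGrowthCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_polynomial(table: ReferenceTable, degree: int = 5) -> MeanGrowthCurve:
    """Fit a degree-``degree`` mean growth curve to a reference table."""
    return MeanGrowthCurve(degree=degree, sex=table.sex).fit(table)


def eval_curve(curve: MeanGrowthCurve, age) -> float:
    """Evaluate a fitted curve at an age (clamped above ``age_max_``)."""
    return curve.predict(age)
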