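"""Prediction-error summaries.

Deviations are always ``predicted - observed`` (positive = overshoot).
A summary bundles the usual regression metrics (MAE, RMSE, max absolute
error), within-threshold accuracies, and the boxplot statistics
(quartiles, IQR, points beyond the 1.5*IQR whiskers).

Quantiles use linear interpolation between order statistics ("type 7",
the numpy default); this is stated because the IQR and hence the outlier
set depend on the convention.  Display rounding is half-away-from-zero to
two decimals; internal arithmetic never rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ErrorSummary", "summarize_errors", "deviation_table",
           "within_fraction", "round_display"]

DEFAULT_THRESHOLDS = (1.0, 2.0, 3.0)


def round_display(x, decimals: int = 2):
    """Round half away from zero (the convention used in printed tables)."""
    arr = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(arr) * np.floor(np.abs(arr) * factor + 0.5) / factor
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def within_fraction(deviations, threshold: float) -> float:
    """Fraction of deviations with ``|d| < threshold``.

    The boundary counts as outside: a deviation of exactly 2 cm is not
    "within 2 cm".
    """
    d = np.asarray(deviations, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty deviation vector")
    return float(np.mean(np.abs(d) < threshold))


@dataclass
class ErrorSummary:
    """Error metrics for one prediction set (all heights in cm)."""

    n: int
    mae: float
    rmse: float
    max_abs: float
    within: dict            # threshold (cm) -> fraction in [0, 1]
    quartiles: tuple        # (q1, median, q3)
    iqr: float
    outliers: list          # deviations beyond the 1.5*IQR whiskers

    def to_dict(self) -> dict:
        return {
            "n": self.n, "mae": self.mae, "rmse": self.rmse,
            "max_abs": self.max_abs,
            "within": {str(k): v for k, v in self.within.items()},
            "quartiles": list(self.quartiles), "iqr": self.iqr,
            "outliers": list(self.outliers),
        }


def summarize_errors(predicted, observed,
                     thresholds=DEFAULT_THRESHOLDS) -> ErrorSummary:
    """Summarise deviations ``predicted - observed``.

    ``thresholds`` sets the within-k-cm accuracy levels (default 1, 2, 3).
    """
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.size != o.size:
        raise ValueError("predicted and observed differ in length")
    if p.size == 0:
        raise ValueError("empty input")
    d = p - o
    q1, med, q3 = np.percentile(d, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return ErrorSummary(
        n=int(d.size),
        mae=float(np.mean(np.abs(d))),
        rmse=float(np.sqrt(np.mean(d ** 2))),
        max_abs=float(np.max(np.abs(d))),
        within={float(t): within_fraction(d, t) for t in thresholds},
        quartiles=(float(q1), float(med), float(q3)),
        iqr=float(iqr),
        outliers=sorted(float(x) for x in d[(d < lo) | (d > hi)]),
    )


def deviation_table(records: pd.DataFrame,
                    predicted_col: str = "predicted_height",
                    observed_col: str = "target_height") -> pd.DataFrame:
    """Per-record deviation table in the worked-example layout.

    Adds ``deviation`` (full precision) and ``deviation_display`` (rounded
    half-away-from-zero to 2 decimals) columns; deviation is
    predicted minus observed target height.
    """
    for col in (predicted_col, observed_col):
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
        if records[col].isna().any():
            raise ValueError(f"column {col!r} has missing values")
    out = records.copy()
    dev = out[predicted_col].to_numpy(float) - out[observed_col].to_numpy(float)
    out["deviation"] = dev
    out["deviation_display"] = round_display(dev, 2)
    return out
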