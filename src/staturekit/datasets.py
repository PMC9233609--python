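"""Bundled tables: synthetic references and worked-example predictions.

The national 0 SD height table, the WHO-style standard-BMI-for-age table
and the Bayley-Pinneau FP table that a real deployment would use are all
licensed publications and are not redistributable, so this module ships
clearly-labelled *synthetic* stand-ins with the right shape and scale:

* mean heights come from a Preece-Baines model-1 curve, tabulated on a
  half-year grid from 6 to 18; the parameter values give realistic
  East-Asian mean statures while keeping the curve flat enough near 18
  (adult height means growth is complete) that a degree-5 polynomial fit
  of the grid stays non-decreasing over the whole domain, the shape
  assumption the per-child registration relies on;
* standard BMI is a gently convex function of age rising from ~15 kg/m^2
  at age 5 to ~21.5 kg/m^2 at 18;
* FP fractions are derived from the synthetic mean curve itself,
  FP(bone age) = f(bone age + shift) / f(18), with the shift encoding the
  developmental category.

Any user-supplied CSV in the documented formats replaces them.

Separately, :func:`load_state_height_examples` returns a bundled worked
example: twenty boys and twenty girls with a current measurement, a
follow-up (target-age) measurement, a model-predicted stage height and
the deviation as originally reported, used in tests and the acceptance
script to exercise the evaluation arithmetic.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import FpTable
from .features import StandardBmiTable
from .reference import ReferenceTable, _check_sex

__all__ = [
    "synthetic_reference_table",
    "synthetic_standard_bmi_table",
    "synthetic_fp_table",
    "write_synthetic_tables",
    "load_state_height_examples",
]

# Preece-Baines model 1: h(t) = h1 - 2(h1 - h_theta) /
#                               (exp(s0 (t - theta)) + exp(s1 (t - theta)))
_PB_PARAMS = {
    "M": dict(h1=174.5, h_theta=163.0, s0=0.12, s1=0.90, theta=13.0),
    "F": dict(h1=162.5, h_theta=152.0, s0=0.16, s1=0.80, theta=10.8),
}

_BMI_PARAMS = {  # bmi(age) = c0 + c1 (age-5) + c2 (age-5)^2
    "M": (15.3, 0.15, 0.027),
    "F": (15.1, 0.12, 0.030),
}

_FP_CATEGORY_SHIFT = {"early": 0.4, "normal": 0.0, "late": -0.4}

AGE_GRID = np.arange(6.0, 18.01, 0.5)


def _preece_baines(t, h1, h_theta, s0, s1, theta):
    t = np.asarray(t, dtype=float)
    return h1 - 2.0 * (h1 - h_theta) / (np.exp(s0 * (t - theta))
                                        + np.exp(s1 * (t - theta)))


def synthetic_reference_table(sex: str) -> ReferenceTable:
    """Synthetic per-sex mean-height (0 SD) grid, ages 4-18 by 0.5 years."""
    _check_sex(sex)
    heights = np.round(_preece_baines(AGE_GRID, **_PB_PARAMS[sex]), 1)
    return ReferenceTable(sex=sex, ages=AGE_GRID.copy(), heights=heights)


def synthetic_standard_bmi_table(sex: str) -> StandardBmiTable:
    """Synthetic per-sex standard BMI-for-age grid, kg/m^2."""
    _check_sex(sex)
    c0, c1, c2 = _BMI_PARAMS[sex]
    u = AGE_GRID - 5.0
    bmi = np.round(c0 + c1 * u + c2 * u ** 2, 2)
    return StandardBmiTable(sex=sex, ages=AGE_GRID.copy(), bmi_values=bmi)


def synthetic_fp_table(sex: str, category: str = "normal") -> FpTable:
    """Synthetic fraction-of-adult-height table derived from the mean curve."""
    shift = _FP_CATEGORY_SHIFT[category]
    p = _PB_PARAMS[sex]
    bone_ages = AGE_GRID.copy()
    adult = _preece_baines(18.0, **p)
    fp = np.minimum(_preece_baines(bone_ages + shift, **p) / adult, 1.0)
    return FpTable(sex=sex, developmental_category=category,
                   bone_ages=bone_ages, fp_values=np.round(fp, 4))


def write_synthetic_tables(out_dir: str | Path) -> dict:
    """Write the synthetic reference/BMI/FP tables as CSVs; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sex in ("M", "F"):
        ref = synthetic_reference_table(sex)
        p = out / f"synthetic_reference_{sex}.csv"
        pd.DataFrame({"age": ref.ages, "height": ref.heights}).to_csv(
            p, index=False)
        paths[f"reference_{sex}"] = p
    bmi_frames = []
    for sex in ("M", "F"):
        t = synthetic_standard_bmi_table(sex)
        bmi_frames.append(pd.DataFrame(
            {"sex": sex, "age": t.ages, "bmi": t.bmi_values}))
    p = out / "synthetic_standard_bmi.csv"
    pd.concat(bmi_frames, ignore_index=True).to_csv(p, index=False)
    paths["bmi"] = p
    fp_frames = []
    for sex in ("M", "F"):
        for cat in _FP_CATEGORY_SHIFT:
            t = synthetic_fp_table(sex, cat)
            fp_frames.append(pd.DataFrame(
                {"sex": sex, "category": cat, "bone_age": t.bone_ages,
                 "fp": t.fp_values}))
    p = out / "synthetic_fp.csv"
    pd.concat(fp_frames, ignore_index=True).to_csv(p, index=False)
    paths["fp"] = p
    return paths


def load_state_height_examples(sex: str) -> pd.DataFrame:
    """Worked-example stage-height predictions for twenty children.

    Columns: ``id, current_age, current_height, target_age, target_height,
    predicted_height, reported_deviation`` (all heights cm, ages years).
    ``reported_deviation`` is the deviation column as originally published
    alongside these predictions; in a minority of rows it differs from
    ``predicted - target`` by 0.01 cm because it was computed upstream
    from unrounded predictions.
    """
    _check_sex(sex)
    name = "state_height_examples_boys.csv" if sex == "M" \
        else "state_height_examples_girls.csv"
    with resources.files("staturekit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)
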