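"""Synthetic longitudinal growth cohorts.

The real cohorts this kind of model is trained on are private clinical
records, so every downstream test and demonstration runs on simulated
children drawn from exactly the generative structure the method assumes:

* each child is a warped copy of the mean curve, heights
  ``f(alpha*age + beta) + gamma`` with per-child (alpha, beta, gamma)
  drawn around (1, 0, 0);
* the true adult height is the child's own curve at age 18,
  ``f(clamp(alpha*18 + beta)) + gamma`` — for a late developer this sits
  slightly below the plateau, exactly the ambiguity the registration's
  least-squares treatment exists to absorb;
* bone age tracks the child's *developmental* age ``alpha*age + beta``
  (an early developer, beta > 0, shows advanced bone age), advanced
  further by adiposity, plus assessment noise;
* weight follows a per-child BMI trajectory (standard BMI-for-age plus a
  stable subject offset) applied to the child's true height, so the BMI
  and delta-BMI features carry real signal;
* observed heights add ~0.5 cm stadiometer noise; the stored truths
  (parameters and adult height) are noise-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .features import StandardBmiTable
from .reference import MeanGrowthCurve, _check_sex

__all__ = ["SimulationConfig", "SyntheticSubject", "simulate_cohort",
           "cohort_frame", "truth_frame", "export_cohort"]


@dataclass
class SimulationConfig:
    """Cohort-generator settings.

    All distributional choices are synthetic-by-construction; the defaults
    are documented in the methods note.  ``noise_sd`` defaults to the
    0.5 cm repeatability of clinical height measurement; ``alpha`` is
    lognormal around 1 with log-sd ``alpha_sd``; ``beta`` and ``gamma``
    are normal around 0.
    """

    n_subjects: int = 400
    sex: str = "M"
    seed: int = 0
    alpha_sd: float = 0.05
    beta_sd: float = 0.8
    gamma_sd: float = 4.0
    noise_sd: float = 0.5
    bone_age_offset_scale: float = 1.0  # years of bone-age advance per year of beta
    bone_age_noise_sd: float = 0.25
    bmi_sd: float = 1.5
    bmi_bone_age_coupling: float = 0.15  # years of bone-age advance per kg/m^2
    n_visits: int = 2
    visit_spacing: float = 1.0
    first_age_range: tuple = (8.0, 15.0)
    adult_age: float = 18.0

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("alpha_sd", "beta_sd", "gamma_sd", "noise_sd",
                     "bone_age_noise_sd", "bmi_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")


@dataclass
class SyntheticSubject:
    """One simulated child: true warp parameters, visits and adult height."""

    subject_id: str
    sex: str
    alpha: float
    beta: float
    gamma: float
    adult_height: float
    visits: list = field(default_factory=list)  # dicts per visit


def _true_height(base: MeanGrowthCurve, alpha, beta, gamma, age):
    t = np.clip(alpha * np.asarray(age, float) + beta,
                base.age_min_, base.age_max_)
    return np.polyval(base.coefficients_, t) + gamma


def simulate_cohort(config: SimulationConfig, base: MeanGrowthCurve,
                    bmi_table: StandardBmiTable) -> list:
    """Draw a cohort of :class:`SyntheticSubject`, deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.first_age_range
    if lo < base.age_min_ or hi > base.age_max_:
        raise ValueError("first_age_range outside the base-curve domain")
    subjects = []
    for i in range(config.n_subjects):
        alpha = float(np.exp(rng.normal(0.0, config.alpha_sd)))
        beta = float(rng.normal(0.0, config.beta_sd))
        gamma = float(rng.normal(0.0, config.gamma_sd))
        bmi_offset = float(rng.normal(0.0, config.bmi_sd))
        first_age = float(rng.uniform(lo, hi - (config.n_visits - 1)
                                      * config.visit_spacing))
        ages = first_age + config.visit_spacing * np.arange(config.n_visits)
        adult = float(_true_height(base, alpha, beta, gamma, config.adult_age))
        subject = SyntheticSubject(
            subject_id=f"{config.sex}{i:05d}", sex=config.sex,
            alpha=alpha, beta=beta, gamma=gamma, adult_height=adult)
        for age in ages:
            h_true = float(_true_height(base, alpha, beta, gamma, age))
            h_obs = h_true + float(rng.normal(0.0, config.noise_sd))
            dev_age = alpha * age + beta  # developmental age
            bone_age = (age
                        + config.bone_age_offset_scale * (dev_age - age)
                        + config.bmi_bone_age_coupling * bmi_offset
                        + float(rng.normal(0.0, config.bone_age_noise_sd)))
            bone_age = float(np.clip(bone_age, 1e-3, 20.0))
            bmi = bmi_table.standard_bmi(float(np.clip(
                age, bmi_table.ages[0], bmi_table.ages[-1]))) + bmi_offset
            bmi = max(bmi, 10.0)
            weight = bmi * (h_true / 100.0) ** 2
            subject.visits.append(dict(
                age=float(age), bone_age=bone_age, height_observed=h_obs,
                height_true=h_true, weight=float(weight)))
        subjects.append(subject)
    return subjects


def cohort_frame(subjects) -> pd.DataFrame:
    """Flatten subjects to the cohort-CSV schema (one row per visit)."""
    rows = []
    for s in subjects:
        for v in s.visits:
            rows.append(dict(subject_id=s.subject_id, sex=s.sex,
                             age=v["age"], bone_age=v["bone_age"],
                             height=v["height_observed"], weight=v["weight"],
                             adult_height=s.adult_height))
    return pd.DataFrame(rows)


def truth_frame(subjects) -> pd.DataFrame:
    """Per-subject ground truth: warp parameters and exact adult height."""
    return pd.DataFrame([dict(subject_id=s.subject_id, sex=s.sex,
                              alpha=s.alpha, beta=s.beta, gamma=s.gamma,
                              adult_height=s.adult_height)
                         for s in subjects])


def export_cohort(subjects, cohort_path: str | Path,
                  truth_path: str | Path) -> None:
    """Write the flat cohort CSV and the keyed truth CSV."""
    if not subjects:
        raise ValueError("no subjects to export")
    cohort_frame(subjects).to_csv(cohort_path, index=False)
    truth_frame(subjects).to_csv(truth_path, index=False)
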