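"""End-to-end workflow: reference -> train -> personalise -> evaluate.

``run_pipeline`` composes the library modules into the full prediction
workflow and writes a deterministic artifact set:

* ``meancurve_{M,F}.json`` — fitted population mean curves;
* ``model_{M,F}.json`` — trained adult-height networks;
* ``curves.csv`` — per-child (alpha, beta, gamma) registrations;
* ``predictions.csv`` — stage-height predictions at each child's
  follow-up age, with deviations;
* ``report.json`` — adult- and stage-height error summaries per sex;
* ``resolved_config.yaml`` and ``manifest.json`` (artifact checksums).

All randomness flows from the single ``seed`` in the config, so a rerun
with identical inputs reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import (synthetic_reference_table, synthetic_standard_bmi_table)
from .evaluate import DEFAULT_THRESHOLDS, deviation_table, summarize_errors
from .features import (FeatureBuilder, load_cohort, load_standard_bmi_table)
from .mlp import BandedMLPRegressor, DEFAULT_ITERATIONS, split_train_validation
from .personal import AnchorSet, PersonalCurve
from .reference import MeanGrowthCurve, fit_polynomial, load_reference_table
from .simulate import SimulationConfig, cohort_frame, simulate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("staturekit")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    File paths left as ``None`` fall back to the bundled synthetic tables
    (reference, standard BMI) or to a simulated cohort.
    """

    out_dir: str = "staturekit_run"
    seed: int = 0
    sexes: tuple = ("M", "F")
    degree: int = 5
    reference_csv: dict = field(default_factory=dict)   # sex -> path
    bmi_csv: str | None = None
    cohort_csv: str | None = None
    simulation: dict = field(default_factory=dict)      # SimulationConfig overrides
    mlp: dict = field(default_factory=dict)             # sex -> param overrides
    split_ratio: float = 0.75
    thresholds: tuple = DEFAULT_THRESHOLDS


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML run config; keyword overrides win over file keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.sexes = tuple(cfg.sexes)
    cfg.thresholds = tuple(cfg.thresholds)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return run
    return wrap


@_stage("reference")
def _fit_references(cfg: RunConfig, out: Path) -> dict:
    curves = {}
    for sex in cfg.sexes:
        path = cfg.reference_csv.get(sex)
        if path is not None:
            table = load_reference_table(path, sex)
        else:
            table = synthetic_reference_table(sex)
        curve = fit_polynomial(table, degree=cfg.degree)
        curve.save(out / f"meancurve_{sex}.json")
        curves[sex] = curve
    return curves


@_stage("tables")
def _load_bmi_tables(cfg: RunConfig) -> dict:
    if cfg.bmi_csv is not None:
        return {sex: load_standard_bmi_table(cfg.bmi_csv, sex)
                for sex in cfg.sexes}
    return {sex: synthetic_standard_bmi_table(sex) for sex in cfg.sexes}


@_stage("cohort")
def _get_cohort(cfg: RunConfig, curves, bmi_tables, out: Path) -> pd.DataFrame:
    if cfg.cohort_csv is not None:
        return load_cohort(cfg.cohort_csv)
    frames = []
    for k, sex in enumerate(cfg.sexes):
        sim_kwargs = dict(cfg.simulation)
        sim_kwargs.update(sex=sex, seed=cfg.seed * 1000 + k)
        sim = SimulationConfig(**sim_kwargs)
        frames.append(cohort_frame(simulate_cohort(sim, curves[sex],
                                                   bmi_tables[sex])))
    cohort = pd.concat(frames, ignore_index=True)
    cohort.to_csv(out / "cohort.csv", index=False)
    return cohort


def _current_and_followup(cohort: pd.DataFrame):
    """Split each subject's visits into the first (current) and last (follow-up)."""
    cohort = cohort.sort_values(["subject_id", "age"], kind="mergesort")
    first = cohort.groupby("subject_id", sort=False).head(1)
    last = cohort.groupby("subject_id", sort=False).tail(1)
    multi = cohort.groupby("subject_id", sort=False)["age"].count() > 1
    followup = last[last["subject_id"].map(multi)]
    return first.reset_index(drop=True), followup.set_index("subject_id")


@_stage("train")
def _train_models(cfg: RunConfig, cohort, bmi_tables, out: Path):
    models, val_sets = {}, {}
    for sex in cfg.sexes:
        sub = cohort[cohort["sex"] == sex]
        current, _ = _current_and_followup(sub)
        if "adult_height" not in current.columns or \
                current["adult_height"].isna().all():
            raise ValueError(f"no adult heights available for sex {sex}")
        current = current.dropna(subset=["adult_height"])
        train, val = split_train_validation(current, ratio=cfg.split_ratio,
                                            seed=cfg.seed + 7)
        builder = FeatureBuilder(bmi_table=bmi_tables[sex]).fit()
        params = dict(hidden_units=100,
                      learning_rate=5e-5,
                      iterations=DEFAULT_ITERATIONS[sex],
                      band=0.5, random_state=cfg.seed + 11,
                      standardize=True)
        params.update(cfg.mlp.get(sex, cfg.mlp.get("all", {})))
        model = BandedMLPRegressor(**params)
        model.fit(builder.transform(train),
                  train["adult_height"].to_numpy(float))
        log.info("trained %s model: final loss %.4f cm^2", sex, model.loss_)
        model.save(out / f"model_{sex}.json")
        models[sex] = model
        val_sets[sex] = val
    return models, val_sets


@_stage("personalize")
def _personalize(cfg: RunConfig, cohort, curves, bmi_tables, models,
                 val_sets, out: Path):
    curve_rows, pred_rows = [], []
    for sex in cfg.sexes:
        sub = cohort[cohort["sex"] == sex]
        _, followup = _current_and_followup(sub)
        builder = FeatureBuilder(bmi_table=bmi_tables[sex]).fit()
        val = val_sets[sex]
        X = builder.transform(val)
        adult_pred = models[sex].predict(X)
        for row, h_final in zip(val.itertuples(index=False), adult_pred):
            anchors = AnchorSet(observations=((row.age, row.height),),
                                adult_height=float(h_final))
            pc = PersonalCurve(base=curves[sex]).fit(anchors)
            curve_rows.append(dict(subject_id=row.subject_id, sex=sex,
                                   alpha=pc.alpha_, beta=pc.beta_,
                                   gamma=pc.gamma_, objective=pc.objective_,
                                   adult_height_pred=float(h_final)))
            if row.subject_id in followup.index:
                fu = followup.loc[row.subject_id]
                pred_rows.append(dict(
                    subject_id=row.subject_id, sex=sex,
                    current_age=row.age, target_age=float(fu["age"]),
                    target_height=float(fu["height"]),
                    predicted_height=pc.predict(float(fu["age"])),
                    adult_height_true=getattr(row, "adult_height", np.nan),
                    adult_height_pred=float(h_final)))
    curves_df = pd.DataFrame(curve_rows)
    curves_df.to_csv(out / "curves.csv", index=False)
    preds = deviation_table(pd.DataFrame(pred_rows)) if pred_rows \
        else pd.DataFrame(pred_rows)
    preds.to_csv(out / "predictions.csv", index=False)
    return curves_df, preds


@_stage("evaluate")
def _evaluate(cfg: RunConfig, preds: pd.DataFrame, out: Path) -> dict:
    report = {}
    for sex in cfg.sexes:
        sub = preds[preds["sex"] == sex] if len(preds) else preds
        entry = {}
        if len(sub):
            entry["stage_height"] = summarize_errors(
                sub["predicted_height"], sub["target_height"],
                cfg.thresholds).to_dict()
            if sub["adult_height_true"].notna().all():
                entry["adult_height"] = summarize_errors(
                    sub["adult_height_pred"], sub["adult_height_true"],
                    cfg.thresholds).to_dict()
        report[sex] = entry
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True))
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow; returns the manifest of produced artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(asdict(config), sort_keys=True))

    curves = _fit_references(config, out)
    bmi_tables = _load_bmi_tables(config)
    cohort = _get_cohort(config, curves, bmi_tables, out)
    models, val_sets = _train_models(config, cohort, bmi_tables, out)
    _personalize(config, cohort, curves, bmi_tables, models, val_sets, out)
    preds = pd.read_csv(out / "predictions.csv")
    _evaluate(config, preds, out)

    artifacts = sorted(p.name for p in out.iterdir()
                       if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
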