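"""Config-driven experiment orchestration.

Reproduces the evaluation grids (architecture x transfer strategy x horizon x
augmentation x loss) on synthetic or user-supplied CGM data: data loading,
smoothing, 0.01 rescaling, windowing/labeling, leave-one-patient-out transfer
evaluation, and collated sweep tables. All randomness derives from the master
seed via counter-based substreams; rerunning an identical resolved config
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .augment import AugmentationPlan
from .cgm_data import (assign_labels, make_segments, read_cgm_csv, rescale,
                       smooth)
from .evalmetrics import EvalReport
from .nets import ModelSpec, TrainConfig
from .seeds import substream
from .synthetic_cgm import SyntheticCohortConfig, simulate_cohort
from .transfer import get_strategy, loocv_evaluate

__all__ = ["ExperimentConfig", "prepare_cohort", "run_experiment", "sweep"]

log = logging.getLogger("glyco")

MODEL_SCALE = 0.01  # BG in model units = 0.01 x mg/dL
SWEEP_AXES = ("n_target_train", "horizon", "fold_k", "alpha", "method", "loss")


@dataclass
class ExperimentConfig:
    """Everything needed to run one evaluation cell (or a sweep around it)."""

    task: str = "regression"            # regression | binary | three_class
    horizons: list[int] = field(default_factory=lambda: [30])
    architecture: str = "CNN"
    strategy: str = "Transfer2"
    n_target_train: int = 250
    input_minutes: int = 30
    smooth_window: int = 3
    hypo_threshold: float = 80.0
    hyper_threshold: float = 180.0
    synthetic: SyntheticCohortConfig | None = field(
        default_factory=SyntheticCohortConfig)
    csv_path: str | None = None         # overrides synthetic when set
    train: TrainConfig = field(default_factory=TrainConfig)
    augmentation: AugmentationPlan = field(default_factory=AugmentationPlan)
    output_dir: str = "glyco-results"
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("regression", "binary", "three_class"):
            raise ValueError(f"unknown task {self.task!r}")
        for h in self.horizons:
            if h % 5 != 0 or not (5 <= h <= 60):
                raise ValueError(
                    f"horizon {h} min invalid: must be a multiple of 5 in [5, 60]")
        get_strategy(self.strategy)

    def resolved(self) -> dict:
        """Every default materialized, for the on-disk config record."""
        return _to_plain(self)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticCohortConfig.from_dict(raw["synthetic"])
        if "train" in raw:
            raw["train"] = TrainConfig(**raw["train"])
        if "augmentation" in raw:
            raw["augmentation"] = AugmentationPlan(**raw["augmentation"])
        return cls(**raw)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj) if not f.name.startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def prepare_cohort(config: ExperimentConfig, horizon: int) -> dict:
    """Load or simulate the cohort and produce labeled, scaled segments."""
    if config.csv_path is not None:
        series_list = read_cgm_csv(config.csv_path)
    else:
        syn = replace(config.synthetic, seed=substream(config.seed, 0))
        series_list = simulate_cohort(syn)
    scheme = "three_class" if config.task == "three_class" else "binary"
    cohort = {}
    for series in series_list:
        s = smooth(series, config.smooth_window)
        s = rescale(s, MODEL_SCALE)
        segs = make_segments(s, input_minutes=config.input_minutes,
                             horizon_minutes=horizon)
        if len(segs) == 0:
            log.info("patient %s: too short for horizon %d, skipped",
                     series.patient_id, horizon)
            continue
        cohort[series.patient_id] = assign_labels(
            segs, config.hypo_threshold, config.hyper_threshold, scheme)
    if len(cohort) < 3:
        raise ValueError("cohort too small after segmentation (need >= 3 patients)")
    return cohort


def _model_spec(config: ExperimentConfig) -> ModelSpec:
    return ModelSpec(architecture=config.architecture, head=config.task)


def run_experiment(config: ExperimentConfig) -> list[EvalReport]:
    """Execute the full pipeline, one LOOCV evaluation per horizon, writing
    per-patient and aggregate reports plus the resolved config."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh, sort_keys=False)
    seed_ledger = {"master_seed": config.seed,
                   "scheme": "SeedSequence([master, *keys]) -> uint32 % 2**31",
                   "synthetic_cohort": substream(config.seed, 0),
                   "train_by_horizon": {h: substream(config.seed, 10, h)
                                        for h in config.horizons}}
    with open(out_dir / "seeds.json", "w") as fh:
        json.dump(seed_ledger, fh, indent=2)

    reports = []
    for horizon in config.horizons:
        log.info("horizon %d min: preparing cohort", horizon)
        cohort = prepare_cohort(config, horizon)
        train_cfg = replace(config.train,
                            seed=substream(config.seed, 10, horizon),
                            augmentation=(config.augmentation
                                          if config.augmentation.method != "none"
                                          else None))
        report = loocv_evaluate(cohort, _model_spec(config), config.strategy,
                                train_cfg, config.n_target_train,
                                hypo_threshold=config.hypo_threshold)
        stem = f"report_h{horizon}"
        report.to_csv(out_dir / f"{stem}.csv")
        report.to_json(out_dir / f"{stem}.json")
        log.info("horizon %d min: %s", horizon, report.aggregate())
        reports.append(report)
    return reports


def augmentation_sensitivity_study(master_seed: int = 0, n_seeds: int = 5,
                                   methods: tuple[str, ...] = ("none", "mixup"),
                                   n_patients: int = 10,
                                   duration_hours: float = 48.0,
                                   horizon: int = 20, n_target_train: int = 250,
                                   n_targets: int = 3, fold_k: int = 2,
                                   alpha: float = 2.0,
                                   epochs: int = 20) -> pd.DataFrame:
    """Scaled-down minority-augmentation study on synthetic cohorts.

    For each master seed: simulate an imbalanced cohort (hypo prevalence
    around 5%), then for each of the first ``n_targets`` patients pretrain a
    regression CNN (REL_MAE) on the other patients — with or without the
    minority augmentation plan — fine-tune with Transfer2 on the target's
    first ``n_target_train`` segments, predict the chronological remainder,
    and pool the binary hypoglycemia confusion counts over targets. Returns
    one row per (seed, method) with sensitivity/PPV/specificity/NPV, so the
    sensitivity gain of augmentation and its PPV trade-off can be read off
    directly.
    """
    from .augment import AugmentationPlan
    from .evalmetrics import ConfusionCounts, classification_metrics, confusion, \
        regression_to_labels
    from .nets import predict
    from .transfer import (apply_strategy, default_finetune_config, fine_tune,
                           pretrain_population)
    from .cgm_data import split_target_patient

    rows = []
    for s in range(n_seeds):
        seed = substream(master_seed, 100, s)
        syn = SyntheticCohortConfig(n_patients=n_patients,
                                    duration_hours=duration_hours,
                                    seed=substream(seed, 0))
        cohort = {}
        for series in simulate_cohort(syn):
            segs = make_segments(rescale(smooth(series), MODEL_SCALE),
                                 horizon_minutes=horizon)
            cohort[series.patient_id] = assign_labels(segs, scheme="binary")
        for method in methods:
            tp = fp = tn = fn = 0
            for ti, target in enumerate(list(cohort)[:n_targets]):
                plan = None
                if method != "none":
                    plan = AugmentationPlan(method=method, fold_k=fold_k,
                                            alpha=alpha,
                                            seed=substream(seed, 5, ti))
                cfg = TrainConfig(epochs=epochs, seed=substream(seed, 1, ti),
                                  augmentation=plan)
                pre = pretrain_population(cohort, target,
                                          ModelSpec(architecture="CNN"), cfg)
                ready = apply_strategy(pre, "Transfer2",
                                       seed=substream(seed, 2, ti))
                tr, te = split_target_patient(cohort[target], n_target_train)
                ft = replace(default_finetune_config(cfg),
                             seed=substream(seed, 3, ti))
                tuned = fine_tune(ready, tr, ft)
                out = predict(tuned, te)
                pred_lab, true_lab = regression_to_labels(
                    out, te.targets, scheme="binary", scale=te.scale)
                c = confusion(pred_lab, true_lab)
                tp, fp, tn, fn = tp + c.tp, fp + c.fp, tn + c.tn, fn + c.fn
            metrics = classification_metrics(ConfusionCounts(tp, fp, tn, fn))
            rows.append({"seed": s, "method": method, "n_positive": tp + fn,
                         **metrics})
    return pd.DataFrame(rows)


def sweep(config: ExperimentConfig, axis: str, values: list) -> pd.DataFrame:
    """One run per value along a single axis; collated aggregate table."""
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r} (one of {SWEEP_AXES})")
    if not values:
        raise ValueError("sweep needs a non-empty list of values")
    rows = []
    for value in values:
        cfg = replace(config)
        if axis == "n_target_train":
            cfg = replace(config, n_target_train=int(value))
        elif axis == "horizon":
            cfg = replace(config, horizons=[int(value)])
        elif axis == "fold_k":
            cfg = replace(config, augmentation=replace(config.augmentation,
                                                       fold_k=int(value)))
        elif axis == "alpha":
            cfg = replace(config, augmentation=replace(config.augmentation,
                                                       alpha=float(value)))
        elif axis == "method":
            cfg = replace(config, augmentation=replace(config.augmentation,
                                                       method=str(value)))
        else:
            cfg = replace(config, train=replace(config.train, loss=str(value)))
        cfg = replace(cfg, output_dir=str(Path(config.output_dir)
                                          / f"{axis}={value}"))
        for report in run_experiment(cfg):
            row = {axis: value, "horizon_minutes": report.horizon_minutes,
                   "strategy": report.strategy,
                   "augmentation": report.augmentation}
            for metric, ms in report.aggregate().items():
                row[f"{metric}_mean"] = ms["mean"]
                row[f"{metric}_sd"] = ms["sd"]
            rows.append(row)
    table = pd.DataFrame(rows)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / f"sweep_{axis}.csv", index=False)
    return table
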