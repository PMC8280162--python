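"""Population pretraining and patient-specific fine-tuning strategies.

A model is first pretrained on the pooled segments of every patient except
the target (per-patient data alone is too small to train even these small
networks well). Four strategies then govern what happens on the target
patient's own training data:

* ``Pretrain``  — no fine-tuning; the population model is used as-is.
* ``Transfer1`` — reuse both parameter groups, retrain both (initialization
  approach).
* ``Transfer2`` — reuse both groups, retrain only the FNN block; the feature
  block stays frozen bit-for-bit.
* ``Transfer3`` — reuse the feature block, reinitialize the FNN block from
  scratch, retrain only the FNN block (feature-extraction approach).

`loocv_evaluate` runs the full leave-one-patient-out protocol: for each
patient in turn, pretrain on everyone else, apply the strategy, fine-tune on
the target's first segments, and test on the chronological remainder,
reporting per-patient metrics and their mean +/- s.d. across patients.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cgm_data import SegmentSet, split_target_patient
from .evalmetrics import (EvalReport, auroc, classification_metrics, confusion,
                          multiclass_accuracy, regression_metrics,
                          regression_to_labels)
from .nets import (ModelSpec, TrainConfig, TrainedModel, build_model, predict,
                   reinitialize_group, train)
from .seeds import substream

__all__ = ["TransferStrategy", "STRATEGIES", "get_strategy",
           "population_training_set", "ohio_population_training_set",
           "pretrain_population", "apply_strategy", "fine_tune",
           "default_finetune_config", "loocv_evaluate"]


@dataclass(frozen=True)
class TransferStrategy:
    """Declarative fine-tuning behavior over the two parameter groups."""

    name: str
    reuse_feature: bool
    reuse_fnn: bool
    reinit_fnn: bool
    trainable_groups: tuple[str, ...]


STRATEGIES = {
    "Pretrain": TransferStrategy("Pretrain", reuse_feature=True, reuse_fnn=True,
                                 reinit_fnn=False, trainable_groups=()),
    "Transfer1": TransferStrategy("Transfer1", reuse_feature=True, reuse_fnn=True,
                                  reinit_fnn=False,
                                  trainable_groups=("feature_block", "fnn_block")),
    "Transfer2": TransferStrategy("Transfer2", reuse_feature=True, reuse_fnn=True,
                                  reinit_fnn=False,
                                  trainable_groups=("fnn_block",)),
    "Transfer3": TransferStrategy("Transfer3", reuse_feature=True, reuse_fnn=False,
                                  reinit_fnn=True,
                                  trainable_groups=("fnn_block",)),
}

_ALIASES = {"pretrain": "Pretrain", "t1": "Transfer1", "t2": "Transfer2",
            "t3": "Transfer3"}


def get_strategy(name: str) -> TransferStrategy:
    key = _ALIASES.get(name.lower(), name)
    if key not in STRATEGIES:
        raise ValueError(f"unknown transfer strategy {name!r}")
    return STRATEGIES[key]


def population_training_set(cohort: dict[str, SegmentSet],
                            target_patient_id: str) -> SegmentSet:
    """Pooled segments of every patient except the target."""
    if target_patient_id not in cohort:
        raise ValueError(f"target patient {target_patient_id!r} not in cohort")
    others = [s for pid, s in cohort.items() if pid != target_patient_id]
    if not others:
        raise ValueError("pretraining needs at least 2 patients in the cohort")
    pooled = SegmentSet.concat(others)
    assert not np.any(pooled.patient_ids == target_patient_id)
    return pooled


def ohio_population_training_set(train_sets: dict[str, SegmentSet],
                                 extra_test_sets: dict[str, SegmentSet],
                                 target_patient_id: str) -> SegmentSet:
    """OhioT1DM-style pretraining pool: every patient's training portion plus
    the earlier release's testing portions, minus the target's training
    portion."""
    if target_patient_id not in train_sets:
        raise ValueError(f"target patient {target_patient_id!r} not in cohort")
    parts = [s for pid, s in train_sets.items() if pid != target_patient_id]
    parts += list(extra_test_sets.values())
    if not parts:
        raise ValueError("empty pretraining pool")
    return SegmentSet.concat(parts)


def pretrain_population(cohort: dict[str, SegmentSet], target_patient_id: str,
                        spec: ModelSpec, config: TrainConfig) -> TrainedModel:
    """Train a fresh model on the pooled cohort excluding the target patient;
    the target's segments are verifiably absent from the training stream."""
    pooled = population_training_set(cohort, target_patient_id)
    model = build_model(spec, seed=config.seed)
    return train(model, pooled, config)


def apply_strategy(pretrained: TrainedModel, strategy: TransferStrategy | str,
                   seed: int = 0) -> TrainedModel:
    """Copy/reinitialize/freeze parameter groups per the strategy flags,
    returning a fine-tune-ready model."""
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    model = pretrained.copy()
    if strategy.reinit_fnn:
        reinitialize_group(model, "fnn_block", seed)
    model.trainable_groups = strategy.trainable_groups
    return model


def fine_tune(model: TrainedModel, target_train_segments: SegmentSet,
              config: TrainConfig) -> TrainedModel:
    """Retrain only the model's trainable groups on the target patient's
    training segments; a no-op for the Pretrain strategy."""
    if not model.trainable_groups:
        return model.copy()
    return train(model, target_train_segments, config)


def default_finetune_config(pretrain_config: TrainConfig) -> TrainConfig:
    """Fine-tuning default: the pretraining optimizer with the learning rate
    reduced 10x and 50 epochs."""
    return replace(pretrain_config, lr=pretrain_config.lr / 10.0, epochs=50)


def _score_patient(model: TrainedModel, test: SegmentSet,
                   hypo_threshold: float = 80.0) -> dict[str, float]:
    head = model.spec.head
    out = predict(model, test)
    row: dict[str, float] = {"n_test": float(len(test))}
    if head == "regression":
        row.update(regression_metrics(out, test.targets, scale=test.scale))
        pred_lab, true_lab = regression_to_labels(out, test.targets,
                                                  hypo_threshold=hypo_threshold,
                                                  scheme="binary",
                                                  scale=test.scale)
        row.update(classification_metrics(confusion(pred_lab, true_lab)))
        row["auroc"] = auroc(-out, true_lab, mode="binary")
    else:
        pred_lab = out.argmax(axis=1)
        true_lab = test.labels
        if head == "binary":
            row.update(classification_metrics(confusion(pred_lab, true_lab)))
            row["auroc"] = auroc(out[:, 1], true_lab, mode="binary")
        else:
            row["accuracy"] = multiclass_accuracy(pred_lab, true_lab)
    return row


def loocv_evaluate(cohort: dict[str, SegmentSet], spec: ModelSpec,
                   strategy: TransferStrategy | str, config: TrainConfig,
                   n_target_train: int,
                   finetune_config: TrainConfig | None = None,
                   hypo_threshold: float = 80.0) -> EvalReport:
    """Leave-one-patient-out evaluation.

    For each patient: pretrain on everyone else, apply the strategy (FNN
    reinitialization seeded per fold), fine-tune on the patient's first
    ``n_target_train`` segments, test on the chronological remainder.
    """
    if len(cohort) < 3:
        raise ValueError("LOOCV needs a cohort of at least 3 patients")
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    horizon = next(iter(cohort.values())).horizon_minutes
    rows = []
    for fold, pid in enumerate(cohort):
        pretrained = pretrain_population(cohort, pid, spec, config)
        ready = apply_strategy(pretrained, strategy,
                               seed=substream(config.seed, 1, fold))
        target_train, target_test = split_target_patient(cohort[pid], n_target_train)
        ft_config = finetune_config or default_finetune_config(config)
        ft_config = replace(ft_config, seed=substream(config.seed, 2, fold))
        if len(target_train) and strategy.trainable_groups:
            tuned = fine_tune(ready, target_train, ft_config)
        else:
            tuned = ready
        if len(target_test) == 0:
            continue
        row = {"patient_id": pid}
        row.update(_score_patient(tuned, target_test, hypo_threshold))
        rows.append(row)
    task = spec.head
    return EvalReport(task=task, horizon_minutes=horizon, strategy=strategy.name,
                      augmentation=(config.augmentation.describe()
                                    if config.augmentation is not None else "none"),
                      per_patient=pd.DataFrame(rows))
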