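"""Classification and regression metrics for glycemic prediction.

Implements the confusion-matrix scores used throughout the package
(sensitivity = TP/(TP+FN), PPV = TP/(TP+FP), specificity = TN/(TN+FP),
NPV = TN/(TN+FN), accuracy = (TP+TN)/total, F1), MAE/RMSE for regression,
a rank-based (Mann-Whitney) AUROC with midrank tie handling including
one-vs-rest for the three-class task, the regression-to-class conversion
at the 80/180 mg/dL thresholds, and paired significance tests comparing
prediction horizons.

Metrics with a zero denominator are reported as NaN ("undefined"), never
coerced to 0 or 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cgm_data import (BinaryLabel, GlycemicLabel, HYPO_THRESHOLD,
                       HYPER_THRESHOLD, classify_bg)

__all__ = ["ConfusionCounts", "EvalReport", "regression_to_labels", "confusion",
           "classification_metrics", "multiclass_accuracy", "regression_metrics",
           "auroc", "roc_points", "compare_horizons", "significance_stars"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def regression_to_labels(predictions, truths, hypo_threshold: float = HYPO_THRESHOLD,
                         hyper_threshold: float = HYPER_THRESHOLD,
                         scheme: str = "binary", scale: float = 1.0):
    """Convert real-valued BG predictions and truths into class labels.

    ``scale`` declares the units of the inputs (1.0 for mg/dL, 0.01 for model
    units); thresholds are always in mg/dL. Binary: BG < hypo_threshold is the
    positive (HYPO) class, a value exactly at the threshold is negative. The
    same conversion is applied to predictions and truths.
    """
    pred = np.asarray(predictions, dtype=np.float64) / scale
    true = np.asarray(truths, dtype=np.float64) / scale
    return (classify_bg(pred, hypo_threshold, hyper_threshold, scheme),
            classify_bg(true, hypo_threshold, hyper_threshold, scheme))


def confusion(pred_labels, true_labels, positive_class: int = int(BinaryLabel.HYPO)
              ) -> ConfusionCounts:
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth label vectors differ in length")
    pp = pred == positive_class
    tp = true == positive_class
    return ConfusionCounts(tp=int(np.sum(pp & tp)), fp=int(np.sum(pp & ~tp)),
                           tn=int(np.sum(~pp & ~tp)), fn=int(np.sum(~pp & tp)))


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Derived rates; zero-denominator metrics come back as NaN."""
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    ppv = _ratio(counts.tp, counts.tp + counts.fp)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    npv = _ratio(counts.tn, counts.tn + counts.fn)
    acc = _ratio(counts.tp + counts.tn, counts.total)
    if np.isnan(sens) or np.isnan(ppv) or (sens + ppv) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * ppv * sens / (ppv + sens)
    return {"accuracy": acc, "sensitivity": sens, "ppv": ppv,
            "specificity": spec, "npv": npv, "f1": f1}


def multiclass_accuracy(pred_labels, true_labels) -> float:
    """Fraction of exactly correct labels (micro accuracy)."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("label vectors must be non-empty and equal length")
    return float(np.mean(pred == true))


def regression_metrics(predictions, truths, scale: float = 1.0) -> dict[str, float]:
    """MAE and RMSE reported in mg/dL (``scale`` declares input units)."""
    pred = np.asarray(predictions, dtype=np.float64) / scale
    true = np.asarray(truths, dtype=np.float64) / scale
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("prediction and truth vectors must be non-empty and equal length")
    err = pred - true
    return {"mae": float(np.mean(np.abs(err))),
            "rmse": float(np.sqrt(np.mean(err ** 2)))}


def _binary_auroc(scores: np.ndarray, positive: np.ndarray) -> float:
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)  # midranks for ties
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auroc(scores, true_labels, mode: str = "binary"):
    """Rank-based AUROC (Mann-Whitney formulation, midrank ties).

    Binary mode: ``scores`` is one score per sample, higher meaning more
    positive (e.g. P(HYPO), or the negated BG prediction). Three-class mode:
    ``scores`` is (n, 3) per-class scores; returns one one-vs-rest AUROC per
    glycemic label.
    """
    true = np.asarray(true_labels)
    if mode == "binary":
        s = np.asarray(scores, dtype=np.float64)
        if s.shape != true.shape:
            raise ValueError("scores and labels differ in length")
        return _binary_auroc(s, true == int(BinaryLabel.HYPO))
    if mode == "three_class":
        s = np.asarray(scores, dtype=np.float64)
        if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] != true.size:
            raise ValueError("three-class mode needs (n, 3) scores")
        return {label.name: _binary_auroc(s[:, label.value], true == label.value)
                for label in GlycemicLabel}
    raise ValueError(f"unknown AUROC mode {mode!r}")


def roc_points(scores, true_labels,
               positive_class: int = int(BinaryLabel.HYPO)) -> pd.DataFrame:
    """ROC curve points (threshold, FPR, TPR) for CSV export / plotting."""
    s = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(true_labels) == positive_class
    order = np.argsort(-s, kind="stable")
    s, pos = s[order], pos[order]
    distinct = np.r_[np.flatnonzero(np.diff(s) != 0), s.size - 1]
    tp = np.cumsum(pos)[distinct]
    fp = np.cumsum(~pos)[distinct]
    n_pos, n_neg = max(int(pos.sum()), 1), max(int((~pos).sum()), 1)
    return pd.DataFrame({"threshold": np.r_[np.inf, s[distinct]],
                         "fpr": np.r_[0.0, fp / n_neg],
                         "tpr": np.r_[0.0, tp / n_pos]})


def significance_stars(p: float) -> str:
    """Star convention: *** p<=0.001, ** p<=0.01, * p<=0.05, '' otherwise."""
    if np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare_horizons(per_patient_scores_by_horizon: dict[int, np.ndarray],
                     baseline_horizon: int, test: str = "t") -> pd.DataFrame:
    """Paired two-sided comparison of per-patient scores at each horizon
    against a baseline horizon.

    Every horizon must cover the same patients in the same order. ``test``
    is ``"t"`` (paired t-test, default) or ``"wilcoxon"`` (signed-rank).
    Returns one row per non-baseline horizon with the p-value and its
    significance tier.
    """
    if baseline_horizon not in per_patient_scores_by_horizon:
        raise ValueError(f"baseline horizon {baseline_horizon} not present")
    base = np.asarray(per_patient_scores_by_horizon[baseline_horizon], dtype=np.float64)
    rows = []
    for horizon, scores in sorted(per_patient_scores_by_horizon.items()):
        if horizon == baseline_horizon:
            continue
        x = np.asarray(scores, dtype=np.float64)
        if x.shape != base.shape:
            raise ValueError("horizons cover different patient sets")
        diff = x - base
        if np.allclose(diff, 0.0):
            p = 1.0
        elif np.ptp(diff) == 0.0:
            p = 0.0  # constant nonzero shift: paired statistic diverges
        elif test == "t":
            p = float(stats.ttest_rel(x, base).pvalue)
        elif test == "wilcoxon":
            p = float(stats.wilcoxon(x, base).pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"horizon_minutes": horizon,
                     "baseline_minutes": baseline_horizon,
                     "mean_difference": float(np.mean(diff)),
                     "p_value": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Per-patient metrics plus mean +/- s.d. aggregates for one experiment
    cell (task x horizon x strategy x augmentation)."""

    task: str
    horizon_minutes: int
    strategy: str | None = None
    augmentation: str | None = None
    per_patient: pd.DataFrame = field(default_factory=pd.DataFrame)

    def aggregate(self) -> dict[str, dict[str, float]]:
        """Mean and population s.d. of every numeric metric across patients."""
        out = {}
        for col in self.per_patient.columns:
            if col == "patient_id":
                continue
            vals = pd.to_numeric(self.per_patient[col], errors="coerce").to_numpy(float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            out[col] = {"mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=0))}
        return out

    def to_csv(self, path) -> None:
        self.per_patient.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {"task": self.task, "horizon_minutes": self.horizon_minutes,
                   "strategy": self.strategy, "augmentation": self.augmentation,
                   "per_patient": self.per_patient.to_dict(orient="records"),
                   "aggregate": self.aggregate()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
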