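"""Binary-classifier evaluation and the repeated-split experiment protocol.

The positive class is label 1 (long-term survival). AUC is the area under
the threshold-swept ROC curve, equal to the Mann-Whitney concordance
probability with ties counted as 1/2. Because single 80/10/10 splits of an
imbalanced cohort are noisy, the headline protocol re-splits the cohort many
times, retrains, and reports metric means and standard deviations over the
repeats.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)

from .datasets import SurvivalLabels, stratified_split
from .network import ModelConfig, predict, train

METRIC_NAMES = ("auc", "acc", "pre", "recall", "f1")


@dataclass
class MetricsReport:
    auc: float
    acc: float
    pre: float
    recall: float
    f1: float
    roc_points: list[tuple[float, float]]
    n_pos: int
    n_neg: int
    precision_undefined: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def confusion_metrics(y_true, y_pred) -> tuple[float, float, float, float]:
    """(acc, pre, recall, f1) at a fixed decision threshold; positive = 1.

    With no predicted positives, precision is undefined and reported as 0
    (flagged by ``evaluate_predictions``).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label/prediction length mismatch")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary")
    if y_true.sum() == 0:
        raise ValueError("no positive samples present")
    acc = accuracy_score(y_true, y_pred)
    pre = precision_score(y_true, y_pred, zero_division=0)
    rec = recall_score(y_true, y_pred, zero_division=0)
    f1 = f1_score(y_true, y_pred, zero_division=0)
    return float(acc), float(pre), float(rec), float(f1)


def roc_auc(y_true, scores) -> tuple[list[tuple[float, float]], float]:
    """ROC points swept over all score thresholds and the AUC (ties = 1/2)."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(y_true).size < 2:
        raise ValueError("ROC/AUC require both classes present")
    fpr, tpr, _ = roc_curve(y_true, scores)
    auc = float(roc_auc_score(y_true, scores))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def evaluate_predictions(y_true, probs, threshold: float = 0.5) -> MetricsReport:
    """Full metrics report for probabilistic predictions on one split."""
    y_true = np.asarray(y_true, dtype=int)
    probs = np.asarray(probs, dtype=float)
    points, auc = roc_auc(y_true, probs)
    y_pred = (probs >= threshold).astype(int)
    acc, pre, rec, f1 = confusion_metrics(y_true, y_pred)
    return MetricsReport(
        auc=auc, acc=acc, pre=pre, recall=rec, f1=f1, roc_points=points,
        n_pos=int(y_true.sum()), n_neg=int((1 - y_true).sum()),
        precision_undefined=bool(y_pred.sum() == 0),
    )


@dataclass
class RepeatedExperimentReport:
    reports: list[MetricsReport]
    mean: dict[str, float]
    sd: dict[str, float]
    n_repeats: int
    base_seed: int
    failures: list[tuple[int, str]]

    def to_json(self, path) -> None:
        payload = {
            "mean": self.mean,
            "sd": self.sd,
            "n_repeats": self.n_repeats,
            "base_seed": self.base_seed,
            "n_failures": len(self.failures),
            "per_repeat": [r.as_dict() for r in self.reports],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _aggregate(reports, n_repeats, base_seed, failures) -> RepeatedExperimentReport:
    mean = {k: float(np.mean([getattr(r, k) for r in reports])) for k in METRIC_NAMES}
    sd = {k: float(np.std([getattr(r, k) for r in reports])) for k in METRIC_NAMES}
    return RepeatedExperimentReport(
        reports=reports, mean=mean, sd=sd, n_repeats=n_repeats,
        base_seed=base_seed, failures=failures,
    )


def repeat_experiment(
    stack, clinical, labels: SurvivalLabels, model_cfg: ModelConfig,
    n_repeats: int = 100, base_seed: int = 0,
) -> RepeatedExperimentReport:
    """Re-split, retrain and evaluate on the test part ``n_repeats`` times.

    Repeat k uses seed ``base_seed + k + 1`` for both the stratified split and
    the model initialization. A failing repeat is recorded and excluded from
    the aggregate.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    y = labels.labels if hasattr(labels, "labels") else np.asarray(labels, int)
    reports: list[MetricsReport] = []
    failures: list[tuple[int, str]] = []
    for k in range(n_repeats):
        seed = base_seed + k + 1
        try:
            split = stratified_split(y, seed=seed)
            cfg_k = replace(model_cfg, seed=seed)
            model = train(stack, clinical, y, split, cfg_k)
            preds = predict(model, stack, clinical, idx=split.test_idx)
            reports.append(evaluate_predictions(y[split.test_idx], preds.probabilities))
        except Exception as exc:  # noqa: BLE001 - repeat isolation by design
            failures.append((seed, str(exc)))
    if not reports:
        raise RuntimeError(f"all {n_repeats} repeats failed: {failures[:3]}")
    return _aggregate(reports, n_repeats, base_seed, failures)


def compare_variants(
    stack, clinical, labels, variants, model_cfg: ModelConfig,
    n_repeats: int = 20, base_seed: int = 0,
) -> dict[str, RepeatedExperimentReport]:
    """Run the repeated-split protocol for several model variants.

    All variants see the same sequence of splits (same per-repeat seeds), so
    differences in the aggregated metrics are paired comparisons.
    """
    out: dict[str, RepeatedExperimentReport] = {}
    for variant in variants:
        cfg_v = replace(model_cfg, variant=variant)
        out[variant] = repeat_experiment(
            stack, clinical, labels, cfg_v, n_repeats=n_repeats, base_seed=base_seed
        )
    return out
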