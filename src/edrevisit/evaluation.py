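"""Balanced undersampling, repeated k-fold cross-validation, and metrics.

The protocol: from an imbalanced cohort, draw ``n_subsets`` balanced
datasets, each containing every positive (30-day revisit) instance plus an
equally sized uniform sample of negatives (independent across subsets, no
replacement within one).  Each balanced dataset is split into ``n_folds``
(stratified by default) folds; every model kind is fitted on the other
folds and scored on the held-out fold, with identical splits across model
kinds.  With the reference settings (5 subsets x 5 folds) each model
accumulates 25 fold scores; reported performance is their mean and SD, and
models are compared with paired two-sided t-tests on fold-aligned scores.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .models import MODEL_KINDS, TrainConfig, predict, train
from .preprocessing import LabeledInstance, PreprocessConfig

__all__ = [
    "EvalConfig",
    "FoldScore",
    "EvaluationReport",
    "TTestResult",
    "UndersamplingError",
    "SingleClassError",
    "make_balanced_subsets",
    "kfold_splits",
    "compute_metrics",
    "run_protocol",
    "paired_ttest",
    "average_roc_curve",
    "write_metrics_csv",
    "write_aggregate_table",
    "write_roc_points",
]

METRIC_NAMES = ("f1", "precision", "recall", "accuracy", "auroc", "ppv", "npv")
TTEST_METRICS = ("f1", "recall", "auroc", "accuracy", "precision")


class UndersamplingError(ValueError):
    """Raised when the majority class is smaller than the minority class."""


class SingleClassError(ValueError):
    """AUROC is undefined on single-class labels; other metrics are carried
    on the exception as ``partial_metrics``."""

    def __init__(self, message: str, partial_metrics: dict | None = None):
        super().__init__(message)
        self.partial_metrics = partial_metrics or {}


@dataclass(frozen=True)
class EvalConfig:
    n_subsets: int = 5
    n_folds: int = 5
    seed: int = 0
    stratified_folds: bool = True

    def __post_init__(self):
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class FoldScore:
    subset: int
    fold: int
    tp: int
    fp: int
    fn: int
    tn: int
    metrics: dict[str, float]
    roc_points: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)
    degenerate: frozenset[str] = frozenset()

    @property
    def test_size(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


@dataclass
class EvaluationReport:
    scores: dict[str, list[FoldScore]]
    aggregates: dict[str, dict[str, tuple[float, float]]]  # kind -> metric -> (mean, sd)
    ttests: dict[tuple[str, str, str], TTestResult]  # (kind_a, kind_b, metric)
    eval_config: EvalConfig
    train_config: TrainConfig


def make_balanced_subsets(instances: Sequence[LabeledInstance], cfg: EvalConfig
                          ) -> list[list[LabeledInstance]]:
    """Draw balanced datasets: all positives plus equal-size negative samples.

    Negatives are sampled uniformly without replacement within each subset
    and independently across subsets, so a negative may recur in different
    subsets.
    """
    pos = [i for i in instances if i.label == 1]
    neg = [i for i in instances if i.label == 0]
    if not pos or not neg:
        raise ValueError("both classes must be present to balance")
    if len(neg) < len(pos):
        raise UndersamplingError(
            f"{len(neg)} negatives < {len(pos)} positives; undersampling assumes "
            "the non-revisit group is the majority"
        )
    rng = np.random.default_rng(cfg.seed)
    subsets = []
    for _ in range(cfg.n_subsets):
        chosen = rng.choice(len(neg), size=len(pos), replace=False)
        subsets.append(list(pos) + [neg[j] for j in chosen])
    return subsets


def kfold_splits(dataset: Sequence[LabeledInstance], cfg: EvalConfig
                 ) -> list[tuple[list[LabeledInstance], list[LabeledInstance]]]:
    """Partition *dataset* into n_folds train/test splits.

    Folds are as equal as integer division allows, stratified by label when
    enabled; every instance lands in exactly one test fold.
    """
    if len(dataset) < cfg.n_folds:
        raise ValueError(f"dataset of {len(dataset)} cannot be split into {cfg.n_folds} folds")
    labels = np.array([i.label for i in dataset])
    if cfg.stratified_folds:
        splitter = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
        iterator = splitter.split(np.zeros(len(dataset)), labels)
    else:
        splitter = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
        iterator = splitter.split(np.zeros(len(dataset)))
    return [
        ([dataset[i] for i in tr], [dataset[i] for i in te])
        for tr, te in iterator
    ]


def compute_metrics(labels: Sequence[int], probabilities: Sequence[float],
                    threshold: float = 0.5) -> FoldScore:
    """All per-fold metrics from labels and predicted probabilities.

    Thresholded counts give precision (= PPV), recall, F1, accuracy and NPV;
    AUROC integrates the ROC curve (trapezoidal), equivalent to the
    concordance probability with ties counted 1/2.  A metric with a zero
    denominator is reported as 0 and flagged in ``degenerate``.

    Raises :class:`SingleClassError` (carrying the threshold metrics) when
    labels contain only one class, since AUROC is then undefined.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))

    degenerate = set()

    def _ratio(num, den, name):
        if den == 0:
            degenerate.add(name)
            return 0.0
        return num / den

    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f1 = _ratio(2 * precision * recall, precision + recall, "f1")
    accuracy = _ratio(tp + tn, len(y), "accuracy")
    npv = _ratio(tn, tn + fn, "npv")
    metrics = {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "accuracy": accuracy,
        "ppv": precision,
        "npv": npv,
    }
    if len(np.unique(y)) < 2:
        raise SingleClassError("AUROC undefined: labels contain a single class",
                               partial_metrics=metrics)
    metrics["auroc"] = float(roc_auc_score(y, p))
    fpr, tpr, _ = roc_curve(y, p)
    return FoldScore(subset=-1, fold=-1, tp=tp, fp=fp, fn=fn, tn=tn,
                     metrics=metrics, roc_points=(fpr, tpr),
                     degenerate=frozenset(degenerate))


def paired_ttest(scores_a: Sequence[float], scores_b: Sequence[float]) -> TTestResult:
    """Paired two-sided t-test on fold-aligned score differences.

    Zero-variance differences are flagged degenerate instead of failing:
    identical scores give t = 0, p = 1; a constant nonzero difference gives
    an infinite statistic with p = 0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t-test needs two equal-length samples of size >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        mean = float(d.mean())
        if math.isclose(mean, 0.0, abs_tol=1e-15):
            return TTestResult(0.0, 1.0, degenerate=True)
        return TTestResult(math.copysign(math.inf, mean), 0.0, degenerate=True)
    res = _stats.ttest_rel(a, b)
    return TTestResult(float(res.statistic), float(res.pvalue))


def _derive_seed(base: int, *parts: int) -> int:
    x = base & 0x7FFFFFFF
    for p in parts:
        x = (x * 1000003 + p + 1) & 0x7FFFFFFF
    return x


def run_protocol(model_kinds: Sequence[str], instances: Sequence[LabeledInstance],
                 train_cfg: TrainConfig, eval_cfg: EvalConfig,
                 preprocess_cfg: PreprocessConfig | None = None,
                 progress=None) -> EvaluationReport:
    """Run the full undersample + repeated k-fold protocol for each model.

    Every model kind sees identical subsets and fold splits; per-fit seeds
    are derived deterministically from the configs so the whole report is
    reproducible from seeds alone.
    """
    for kind in model_kinds:
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}")
    pp = preprocess_cfg or PreprocessConfig()
    subsets = make_balanced_subsets(instances, eval_cfg)
    scores: dict[str, list[FoldScore]] = {k: [] for k in model_kinds}
    for s, subset in enumerate(subsets):
        fold_cfg = EvalConfig(
            n_subsets=eval_cfg.n_subsets, n_folds=eval_cfg.n_folds,
            seed=_derive_seed(eval_cfg.seed, s),
            stratified_folds=eval_cfg.stratified_folds,
        )
        splits = kfold_splits(subset, fold_cfg)
        for f, (tr, te) in enumerate(splits):
            from .preprocessing import fit_schema

            schema = fit_schema(tr, pp)
            for m, kind in enumerate(model_kinds):
                cfg = TrainConfig(
                    epochs=train_cfg.epochs, batch_size=train_cfg.batch_size,
                    learning_rate=train_cfg.learning_rate,
                    hidden_width=train_cfg.hidden_width,
                    seed=_derive_seed(train_cfg.seed, s, f, m),
                    threshold=train_cfg.threshold,
                    gnn_aggregate=train_cfg.gnn_aggregate,
                    gnn_readout=train_cfg.gnn_readout,
                    rnn_cell=train_cfg.rnn_cell,
                )
                try:
                    predictor = train(kind, tr, cfg, schema=schema, preprocess_cfg=pp)
                    probs, _ = predict(predictor, te)
                    score = compute_metrics([i.label for i in te], probs, cfg.threshold)
                except (ValueError, SingleClassError) as exc:
                    raise type(exc)(f"subset {s} fold {f} model {kind}: {exc}") from exc
                score.subset, score.fold = s, f
                scores[kind].append(score)
                if progress is not None:
                    progress(kind, s, f, score)

    aggregates = {
        kind: {
            metric: (
                float(np.mean([sc.metrics[metric] for sc in kind_scores])),
                float(np.std([sc.metrics[metric] for sc in kind_scores], ddof=1))
                if len(kind_scores) > 1 else 0.0,
            )
            for metric in METRIC_NAMES
        }
        for kind, kind_scores in scores.items()
    }
    ttests: dict[tuple[str, str, str], TTestResult] = {}
    kinds = list(model_kinds)
    for i, ka in enumerate(kinds):
        for kb in kinds[i + 1:]:
            for metric in TTEST_METRICS:
                ttests[(ka, kb, metric)] = paired_ttest(
                    [sc.metrics[metric] for sc in scores[ka]],
                    [sc.metrics[metric] for sc in scores[kb]],
                )
    return EvaluationReport(scores, aggregates, ttests, eval_cfg, train_cfg)


def average_roc_curve(fold_scores: Sequence[FoldScore], n_grid: int = 101
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Vertically average per-fold ROC curves on a fixed FPR grid."""
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = []
    for sc in fold_scores:
        fpr, tpr = sc.roc_points
        tprs.append(np.interp(grid, fpr, tpr))
    return grid, np.mean(tprs, axis=0)


def write_metrics_csv(report: EvaluationReport, path) -> None:
    """Long-format per-fold metrics: model, subset, fold, metric, value."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["model", "subset", "fold", "metric", "value"])
        for kind, kind_scores in report.scores.items():
            for sc in kind_scores:
                for metric in METRIC_NAMES:
                    writer.writerow([kind, sc.subset, sc.fold, metric,
                                     repr(sc.metrics[metric])])


def write_aggregate_table(report: EvaluationReport, path) -> None:
    """Aggregate table: mean (SD) per model across all fold scores."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["model", "f1_mean", "f1_sd", "precision", "recall",
                         "auroc", "accuracy_pct", "ppv_pct", "npv_pct"])
        for kind, agg in report.aggregates.items():
            writer.writerow([
                kind,
                f"{agg['f1'][0]:.4f}", f"{agg['f1'][1]:.4f}",
                f"{agg['precision'][0]:.4f}", f"{agg['recall'][0]:.4f}",
                f"{agg['auroc'][0]:.4f}",
                f"{agg['accuracy'][0] * 100:.2f}",
                f"{agg['ppv'][0] * 100:.2f}", f"{agg['npv'][0] * 100:.2f}",
            ])


def write_roc_points(report: EvaluationReport, path, n_grid: int = 101) -> None:
    """Averaged ROC curve per model as (model, fpr, tpr) rows."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["model", "fpr", "tpr"])
        for kind, kind_scores in report.scores.items():
            grid, tpr = average_roc_curve(kind_scores, n_grid)
            for x, y in zip(grid, tpr):
                writer.writerow([kind, f"{x:.6f}", f"{y:.6f}"])
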