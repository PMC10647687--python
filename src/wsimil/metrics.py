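"""Monte Carlo cross-validation and evaluation statistics.

The cohort is split at the patient level into training (70 %), validation
(10 %) and test (20 %) parts, independently per class so the class ratio is
preserved, and the whole train/evaluate cycle is repeated over many runs.
Headline statistics follow the standard definitions: balanced accuracy
BA = (sensitivity + specificity) / 2; ROC curves of sensitivity against
specificity with trapezoidal AUC; the mean ROC curve averaged pointwise over
runs on a fixed specificity grid; and 95 % confidence intervals of the form
mean +/- 1.96 * sample standard deviation across runs.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from sklearn import metrics as skm

from .datatypes import (
    FeatureBag,
    RunMetrics,
    SplitPlan,
    StratificationError,
    TrainConfig,
    UndefinedMetricError,
)
from .model import forward_bag, predict_label, train_model

__all__ = [
    "monte_carlo_splits",
    "confusion_counts",
    "balanced_accuracy",
    "roc_auc",
    "mean_roc_curve",
    "ci95_summary",
    "grade_sensitivity_difference",
    "evaluate_run",
    "run_monte_carlo",
]

#: common specificity grid for averaging ROC curves across runs
SPECIFICITY_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


def _split_counts(n: int) -> tuple[int, int, int]:
    """Per-class train/val/test sizes: round(0.7n) / round(0.1n) / remainder.

    Guards keep every part non-empty down to the minimum class size of 5.
    """
    n_train = int(round(0.7 * n))
    n_val = max(1, int(round(0.1 * n)))
    if n_train + n_val >= n:
        n_train = n - n_val - 1
    return n_train, n_val, n - n_train - n_val


def monte_carlo_splits(cohort: dict, n_runs: int, seed: int) -> list[SplitPlan]:
    """Stratified 70/10/20 patient-level splits for ``n_runs`` runs.

    ``cohort`` maps patient id -> class label.  Each class is partitioned
    independently; parts are disjoint and exhaust the cohort.  Deterministic
    given ``seed``.
    """
    by_class: dict = {}
    for pid, cls in cohort.items():
        by_class.setdefault(cls, []).append(pid)
    for cls, pids in by_class.items():
        if len(pids) < 5:
            raise StratificationError(
                f"class {cls!r} has {len(pids)} patients; need >= 5")
    rng = np.random.default_rng(seed)
    plans = []
    for run in range(n_runs):
        train, val, test = {}, {}, {}
        for cls in sorted(by_class, key=str):
            pids = sorted(by_class[cls])
            perm = rng.permutation(len(pids))
            n_tr, n_va, _ = _split_counts(len(pids))
            order = [pids[i] for i in perm]
            train[cls] = order[:n_tr]
            val[cls] = order[n_tr:n_tr + n_va]
            test[cls] = order[n_tr + n_va:]
        plans.append(SplitPlan(run=run, seed=seed, train=train, val=val, test=test))
    return plans


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray,
                     positive: int = 1) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with respect to the given positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    return tp, fp, tn, fn


def balanced_accuracy(tp: int, fp: int, tn: int, fn: int) -> float:
    """BA = (sensitivity + specificity) / 2 from confusion counts."""
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedMetricError("a class is empty; BA undefined")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return (sens + spec) / 2.0


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC for positive-class scores.

    Returns (points, auc): ``points`` has columns (threshold, sensitivity,
    specificity), swept over all distinct score thresholds.  The AUC equals
    the pair-counting Mann-Whitney statistic with ties counted 1/2.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("need both classes for a ROC curve")
    fpr, tpr, thresholds = skm.roc_curve(labels, scores)
    points = np.column_stack([thresholds, tpr, 1.0 - fpr])
    auc = float(skm.roc_auc_score(labels, scores))
    return points, auc


def mean_roc_curve(curves: Sequence[np.ndarray]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and standard deviation of ROC curves across runs.

    Each curve (threshold, sensitivity, specificity) is interpolated onto the
    common specificity grid (0, 0.01, ..., 1), collapsing duplicate
    specificities to their best sensitivity; returns (grid, mean, std) with
    std the sample standard deviation over curves.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to average")
    interp = []
    for pts in curves:
        sens, spec = np.asarray(pts)[:, 1], np.asarray(pts)[:, 2]
        order = np.argsort(spec, kind="stable")
        spec, sens = spec[order], sens[order]
        uniq_spec, inverse = np.unique(spec, return_inverse=True)
        best = np.full(len(uniq_spec), -np.inf)
        np.maximum.at(best, inverse, sens)
        interp.append(np.interp(SPECIFICITY_GRID, uniq_spec, best))
    interp = np.asarray(interp)
    return SPECIFICITY_GRID, interp.mean(axis=0), interp.std(axis=0, ddof=1)


def ci95_summary(values: Sequence[float]) -> tuple[float, float]:
    """Mean and 1.96 * sample standard deviation of per-run metric values."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    return float(values.mean()), float(1.96 * values.std(ddof=1))


def grade_sensitivity_difference(runs: Sequence[tuple], positive: int = 1,
                                 grades: tuple = (1, 2)) -> np.ndarray:
    """Per-run |sensitivity(grade a) - sensitivity(grade b)| within the
    positive class.

    ``runs`` holds (y_true, y_pred, grade) triples for each run's evaluation
    cohort; values near zero indicate that classification of the class does
    not depend on tumor grade.  Runs where either grade subgroup is empty
    are skipped with a warning.
    """
    diffs = []
    for r, (y_true, y_pred, grade) in enumerate(runs):
        y_true, y_pred, grade = map(np.asarray, (y_true, y_pred, grade))
        sens = []
        for g in grades:
            sel = (y_true == positive) & (grade == g)
            if not sel.any():
                warnings.warn(f"run {r}: grade {g} subgroup empty; run skipped")
                sens = None
                break
            sens.append(np.mean(y_pred[sel] == positive))
        if sens is not None:
            diffs.append(abs(sens[0] - sens[1]))
    return np.asarray(diffs)


def evaluate_run(params: dict, bags: Sequence[FeatureBag],
                 labels: Sequence[int], eval_idx: Sequence[int],
                 run: int = 0) -> RunMetrics:
    """Forward the evaluation bags through a trained model and score the run.

    The ROC score for each patient is the positive class's softmax
    probability (class index 1); the hard decision is the argmax.
    """
    labels = np.asarray(labels)
    y_true = labels[list(eval_idx)]
    probs = np.stack([forward_bag(bags[i], params).probabilities
                      for i in eval_idx])
    y_pred = np.array([predict_label(p) for p in probs])
    tp, fp, tn, fn = confusion_counts(y_true, y_pred, positive=1)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    points, auc = roc_auc(probs[:, 1], y_true)
    return RunMetrics(run=run, tp=tp, fp=fp, tn=tn, fn=fn,
                      sensitivity=sens, specificity=spec,
                      balanced_accuracy=(sens + spec) / 2.0,
                      roc_points=points, auc=auc)


def run_monte_carlo(bags: Sequence[FeatureBag], labels: Sequence[int],
                    n_runs: int, config: TrainConfig, seed: int,
                    eval_part: str = "test"):
    """Full Monte Carlo cross-validation: split, train, evaluate per run.

    Returns (metrics, plans, models): one :class:`RunMetrics`, one
    :class:`SplitPlan` and one parameter checkpoint per run.  Each run's
    training seed is derived from ``seed`` and the run index.
    """
    labels = np.asarray(labels)
    cohort = {bag.patient_id: int(labels[i]) for i, bag in enumerate(bags)}
    pid_to_idx = {bag.patient_id: i for i, bag in enumerate(bags)}
    plans = monte_carlo_splits(cohort, n_runs, seed)
    all_metrics, models = [], []
    for plan in plans:
        tr = [pid_to_idx[p] for p in plan.part_patients("train")]
        va = [pid_to_idx[p] for p in plan.part_patients("val")]
        ev = [pid_to_idx[p] for p in plan.part_patients(eval_part)]
        cfg = TrainConfig(**{**config.__dict__, "seed": (seed + plan.run) % (2 ** 31)})
        params, _ = train_model(bags, labels, tr, va, cfg)
        all_metrics.append(evaluate_run(params, bags, labels, ev, run=plan.run))
        models.append(params)
    return all_metrics, plans, models
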