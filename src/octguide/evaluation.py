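"""Subject-grouped nested cross-validation and cross-testing.

The outer loop rotates every subject through the test role; within each
outer fold the remaining subjects form an inner cross-validation loop in
which each of them validates exactly once while the others train.  Each
candidate architecture is trained in every inner rotation; the architecture
with the best mean inner metric is selected, retrained on the
cross-validation subjects, and scored once on the held-out test subject.
Per-fold test metrics are aggregated as mean +- standard error.

Subject leakage (a test subject appearing in any training or validation
set) is audited on every training run and aborts the evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import FoldSummary, RegressionResult, aggregate_mean_se
from .models import (TrainingConfig, predict_distance, predict_proba,
                     stage_binary_labels, stage_frames, train_classifier,
                     train_regressor)
from .synthetic_data import TissueLabel

__all__ = [
    "FoldPlan", "NestedResult", "LeakageError", "make_nested_folds",
    "run_nested_evaluation", "select_best_architecture",
    "build_sequential_report",
]


class LeakageError(RuntimeError):
    """A held-out subject leaked into a training or validation set."""


@dataclass(frozen=True)
class FoldPlan:
    """One outer rotation: a test subject plus the inner (val, train) pairs."""

    outer_test_subject: object
    inner: tuple            # of (validation_subject, tuple(train_subjects))

    def audit(self):
        for val, train in self.inner:
            if self.outer_test_subject in train or \
                    self.outer_test_subject == val:
                raise LeakageError(
                    f"test subject {self.outer_test_subject} leaked into an "
                    f"inner rotation")
            if val in train:
                raise LeakageError(
                    f"validation subject {val} leaked into its training set")


@dataclass
class NestedResult:
    """Everything the nested protocol produces."""

    task: str
    direction: str                         # 'maximize' | 'minimize'
    inner_metrics: dict                    # {test_subject: {arch: [metrics]}}
    selected: dict                         # {test_subject: arch}
    test_metrics: dict                     # {test_subject: float}
    summary: FoldSummary
    fold_plans: list = field(default_factory=list)


def make_nested_folds(subject_ids: Sequence) -> list:
    """One :class:`FoldPlan` per subject; with n subjects each plan holds
    n-1 inner rotations of (1 validation, n-2 training) subjects."""
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject IDs")
    if len(ids) < 3:
        raise ValueError("nested folds need at least 3 subjects")
    plans = []
    for test in ids:
        cv = [s for s in ids if s != test]
        inner = tuple((val, tuple(s for s in cv if s != val)) for val in cv)
        plan = FoldPlan(outer_test_subject=test, inner=inner)
        plan.audit()
        plans.append(plan)
    return plans


def select_best_architecture(inner_metrics: dict, direction: str) -> str:
    """Architecture with the best mean inner-fold metric.

    ``direction='maximize'`` for accuracy, ``'minimize'`` for MAPE.  Exact
    ties go to the earlier entry in input order.
    """
    if not inner_metrics:
        raise ValueError("no architectures to select from")
    lengths = {len(v) for v in inner_metrics.values()}
    if len(lengths) != 1:
        raise ValueError("unequal inner fold counts across architectures")
    if direction not in ("maximize", "minimize"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "maximize" else -1.0
    best_name, best_val = None, -np.inf
    for name, vals in inner_metrics.items():
        m = sign * float(np.mean(vals))
        if m > best_val:
            best_name, best_val = name, m
    return best_name


def _task_frames(frames, task):
    if task == "multiclass":
        return list(frames)
    if task == "regression":
        return [f for f in frames if f.label == TissueLabel.EPIDURAL_SPACE]
    return stage_frames(frames, int(task[5:]))


def _score(model, frames, task):
    if task == "regression":
        pred = predict_distance(model, frames)
        truth = [f.distance_um for f in frames]
        return RegressionResult(tuple(truth), tuple(pred)).mape
    proba = predict_proba(model, frames)
    if task == "multiclass":
        truth = np.array([int(f.label) for f in frames])
    else:
        truth = stage_binary_labels(frames, int(task[5:]))
    return float((proba.argmax(axis=1) == truth).mean())


def _audit_no_leak(test_subject, train_frames, val_frames):
    used = {f.subject_id for f in train_frames} | \
           {f.subject_id for f in val_frames}
    if test_subject in used:
        raise LeakageError(
            f"test subject {test_subject} found in a training run")


def run_nested_evaluation(frames: Sequence,
                          task: str,
                          architectures: Sequence[str],
                          config: Optional[TrainingConfig] = None,
                          seed: int = 0,
                          subjects: Optional[Sequence] = None) -> NestedResult:
    """Execute the full nested protocol on a frame collection.

    ``task`` is one of ``stage1``..``stage4``, ``multiclass`` or
    ``regression``.  Classification selects by inner validation accuracy
    (maximized); regression by inner MAPE (minimized).  The selected
    architecture is retrained on the cross-validation subjects (for
    classification one CV subject stays out as the early-stopping
    validation set; regression has a fixed epoch budget and trains on all
    of them) and scored once on the unseen test subject.
    """
    config = config or TrainingConfig()
    architectures = list(architectures)
    if subjects is None:
        subjects = sorted({f.subject_id for f in frames})
    by_subject = {s: [f for f in frames if f.subject_id == s]
                  for s in subjects}
    plans = make_nested_folds(subjects)

    direction = "minimize" if task == "regression" else "maximize"
    is_reg = task == "regression"
    trainer = train_regressor if is_reg else train_classifier

    def fit(arch, train_subj, val_subj, run_seed):
        cfg = TrainingConfig(**{**config.__dict__, "architecture": arch})
        train = _task_frames(sum((by_subject[s] for s in train_subj), []),
                             task)
        val = _task_frames(by_subject[val_subj], task) if val_subj else []
        if is_reg:
            return trainer(cfg, train, val, seed=run_seed)
        return trainer(cfg, task, train, val, seed=run_seed)

    inner_metrics, selected, test_metrics = {}, {}, {}
    for oi, plan in enumerate(plans):
        test_subject = plan.outer_test_subject
        plan.audit()
        per_arch = {a: [] for a in architectures}
        for ai, arch in enumerate(architectures):
            for ii, (val_subj, train_subj) in enumerate(plan.inner):
                _audit_no_leak(test_subject,
                               sum((by_subject[s] for s in train_subj), []),
                               by_subject[val_subj])
                run_seed = (seed + 100_000 * oi + 1_000 * ai + ii) % (2**31)
                model = fit(arch, train_subj, val_subj, run_seed)
                per_arch[arch].append(
                    _score(model, _task_frames(by_subject[val_subj], task),
                           task))
        inner_metrics[test_subject] = per_arch
        best = select_best_architecture(per_arch, direction)
        selected[test_subject] = best

        # retrain the winner on the CV subjects, then score the test subject
        cv_subjects = [s for s in subjects if s != test_subject]
        retrain_seed = (seed + 100_000 * oi + 77_777) % (2**31)
        if is_reg:
            model = fit(best, cv_subjects, None, retrain_seed)
        else:
            val_subj = plan.inner[0][0]
            model = fit(best, [s for s in cv_subjects if s != val_subj],
                        val_subj, retrain_seed)
        _audit_no_leak(test_subject,
                       sum((by_subject[s] for s in model.train_subjects
                            if s in by_subject), []), [])
        test_frames = _task_frames(by_subject[test_subject], task)
        test_metrics[test_subject] = _score(model, test_frames, task)

    summary = aggregate_mean_se(list(test_metrics.values()))
    return NestedResult(task=task, direction=direction,
                        inner_metrics=inner_metrics, selected=selected,
                        test_metrics=test_metrics, summary=summary,
                        fold_plans=plans)


GAP_MARKER = "missing"


def build_sequential_report(stage_results: dict,
                            percent: bool = True) -> pd.DataFrame:
    """Cross-testing report: rows = testing folds, columns = stage tasks,
    marginal 'Average' row/column formatted 'mean ± SE'.

    ``stage_results`` maps column name -> {fold label -> metric}.  Missing
    cells appear as the explicit marker ``'missing'`` and are excluded from
    the marginals.
    """
    if not stage_results:
        raise ValueError("no stage results")
    columns = list(stage_results)
    folds = sorted({f for col in stage_results.values() for f in col})
    scale = 100.0 if percent else 1.0

    table = pd.DataFrame(index=folds, columns=columns, dtype=object)
    for col, vals in stage_results.items():
        for fold in folds:
            v = vals.get(fold)
            table.loc[fold, col] = (GAP_MARKER if v is None
                                    else float(v) * scale)

    def fmt(values):
        vals = [v for v in values if v != GAP_MARKER]
        if not vals:
            return GAP_MARKER
        s = aggregate_mean_se(vals)
        return f"{s.mean:.2f} ± {s.se:.2f}"

    table["Average"] = [fmt(table.loc[f, columns]) for f in folds]
    avg_row = {c: fmt(table[c][table[c] != GAP_MARKER]) for c in columns}
    # the grand cell aggregates the per-fold averages, as in the study tables
    row_means = []
    for f in folds:
        vals = [v for v in table.loc[f, columns] if v != GAP_MARKER]
        if vals:
            row_means.append(float(np.mean(vals)))
    avg_row["Average"] = fmt(row_means)
    table.loc["Average"] = avg_row
    return table
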