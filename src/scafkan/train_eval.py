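"""Stratified cross-validation harness, model comparison, baselines.

The evaluation protocol mirrors standard leakage-safe practice: within
each of K stratified folds, imputation/transform/standardisation are
fitted on the training rows only, minority oversampling is applied to the
training rows only, and the untouched validation rows are scored with the
frozen preprocessing state.  A fingerprint of the rows each preprocessor
was fitted on is checked against the fold plan; any mismatch aborts the
run.

Fold-wise model comparison uses paired t-tests and paired Cohen's d
(mean of fold AUC differences over their sample SD).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortTable
from .metrics import MetricSet, compute_metrics, roc_points
from .preprocess import (ResampleConfig, apply_preprocessor, fit_preprocessor,
                         oversample_minority, _rows_fingerprint)

__all__ = ["FoldPlan", "make_folds", "EvalReport", "ComparisonResult",
           "cross_validate", "compare_models", "holm_adjust", "run_baselines"]

logger = logging.getLogger(__name__)

#: model_fn(X_train, y_train, X_val, y_val, seed) -> validation probabilities
ModelFn = Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int], np.ndarray]


@dataclass(frozen=True)
class FoldPlan:
    """Stratified K-fold partition of the cohort rows."""

    K: int
    folds: tuple[tuple[np.ndarray, np.ndarray], ...]   # (train_idx, val_idx) per fold
    labels: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        n = len(self.labels)
        all_val = np.concatenate([v for _, v in self.folds])
        if sorted(all_val.tolist()) != list(range(n)):
            raise ValueError("validation folds must partition all rows")
        for tr, va in self.folds:
            if np.intersect1d(tr, va).size:
                raise ValueError("train and validation overlap within a fold")


def make_folds(labels: np.ndarray, K: int = 5, seed: int = 0) -> FoldPlan:
    labels = np.asarray(labels, int)
    if K < 2:
        raise ValueError("cross-validation requires K >= 2")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < K:
        raise ValueError("each class needs at least K members")
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    folds = tuple((tr.copy(), va.copy()) for tr, va in
                  skf.split(np.zeros(len(labels)), labels))
    return FoldPlan(K=K, folds=folds, labels=labels, seed=seed)


@dataclass
class EvalReport:
    """Per-fold and aggregate evaluation of one model under one fold plan."""

    model_name: str
    plan: FoldPlan
    fold_metrics: list[MetricSet]
    fold_probabilities: list[np.ndarray]
    fold_labels: list[np.ndarray]

    @property
    def fold_aucs(self) -> np.ndarray:
        return np.array([m.auc for m in self.fold_metrics])

    def aggregate(self) -> dict[str, tuple[float, float]]:
        out = {}
        for key in ("auc", "accuracy", "precision", "recall", "f1"):
            vals = np.array([getattr(m, key) for m in self.fold_metrics])
            out[key] = (float(vals.mean()), float(vals.std(ddof=1)))
        return out

    def roc_data(self, fold: int) -> np.ndarray:
        return roc_points(self.fold_labels[fold], self.fold_probabilities[fold])

    def histogram_data(self, fold: int, bins: int = 10):
        p = self.fold_probabilities[fold]
        y = self.fold_labels[fold]
        edges = np.linspace(0, 1, bins + 1)
        return {"edges": edges,
                "positive": np.histogram(p[y == 1], bins=edges)[0],
                "negative": np.histogram(p[y == 0], bins=edges)[0]}

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [f"{self.model_name}: {self.plan.K}-fold cross-validation",
                 "-" * 48]
        lines.append("fold   AUC     ACC     Prec    Rec     F1")
        for i, m in enumerate(self.fold_metrics):
            lines.append(f"{i + 1:>4}  {m.auc:.4f}  {m.accuracy:.4f}  "
                         f"{m.precision:.4f}  {m.recall:.4f}  {m.f1:.4f}")
        lines.append("-" * 48)
        lines.append("mean  " + "  ".join(f"{agg[k][0]:.4f}" for k in
                                          ("auc", "accuracy", "precision",
                                           "recall", "f1")))
        lines.append("  sd  " + "  ".join(f"{agg[k][1]:.4f}" for k in
                                          ("auc", "accuracy", "precision",
                                           "recall", "f1")))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"model": self.model_name,
                "folds": [m.as_dict() for m in self.fold_metrics],
                "aggregate": {k: {"mean": v[0], "sd": v[1]}
                              for k, v in self.aggregate().items()}}


@dataclass
class ComparisonResult:
    """Paired fold-wise comparison of two models' AUCs."""

    model_a: str
    model_b: str
    t_statistic: float
    p_value: float
    cohens_d: float
    fold_differences: np.ndarray


def compare_models(a: EvalReport, b: EvalReport) -> ComparisonResult:
    if a.plan is not b.plan and not all(
            np.array_equal(va, vb) for (_, va), (_, vb)
            in zip(a.plan.folds, b.plan.folds)):
        raise ValueError("reports must share the same fold plan")
    diff = a.fold_aucs - b.fold_aucs
    sd = diff.std(ddof=1)
    if np.allclose(diff, 0.0):
        return ComparisonResult(a.model_name, b.model_name, 0.0, 1.0, 0.0, diff)
    if sd == 0:
        warnings.warn("constant fold differences: Cohen's d is infinite")
        d = np.inf if diff.mean() > 0 else -np.inf
        return ComparisonResult(a.model_name, b.model_name, d, 0.0, d, diff)
    t, p = stats.ttest_rel(a.fold_aucs, b.fold_aucs)
    return ComparisonResult(a.model_name, b.model_name, float(t), float(p),
                            float(diff.mean() / sd), diff)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (reported as a labelled extension column)."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def cross_validate(model_fn: ModelFn, cohort: CohortTable,
                   K: int = 5, seed: int = 0,
                   model_name: str = "model",
                   resample: Optional[ResampleConfig] = None,
                   oversample: bool = True,
                   plan: Optional[FoldPlan] = None) -> EvalReport:
    """Leakage-safe K-fold evaluation of ``model_fn`` on a cohort."""
    if plan is None:
        plan = make_folds(cohort.labels, K, seed)
    fold_metrics, fold_probs, fold_labels = [], [], []
    for f, (tr_idx, va_idx) in enumerate(plan.folds):
        train = CohortTable(cohort.values[tr_idx], cohort.labels[tr_idx],
                            cohort.schema)
        val = CohortTable(cohort.values[va_idx], cohort.labels[va_idx],
                          cohort.schema)
        state = fit_preprocessor(train, fold_id=f"fold{f}")
        expected = _rows_fingerprint(train.values, train.labels, f"fold{f}")
        leaky = _rows_fingerprint(cohort.values, cohort.labels, f"fold{f}")
        if state.fingerprint != expected or state.fingerprint == leaky:
            raise RuntimeError(f"leakage guard: preprocessor of fold {f} was "
                               "not fitted on exactly the training rows")
        X_tr = apply_preprocessor(state, train)
        X_va = apply_preprocessor(state, val)
        y_tr, y_va = train.labels, val.labels
        if oversample:
            cfg = resample or ResampleConfig(seed=seed * 1000 + f)
            X_tr, y_tr = oversample_minority(X_tr, y_tr, cfg)
        p_va = model_fn(X_tr, y_tr, X_va, y_va, seed * 100 + f)
        fold_metrics.append(compute_metrics(y_va, p_va))
        fold_probs.append(np.asarray(p_va, float))
        fold_labels.append(y_va)
    return EvalReport(model_name, plan, fold_metrics, fold_probs, fold_labels)


def run_baselines(cohort: CohortTable, plan: FoldPlan,
                  roster: Optional[dict[str, ModelFn]] = None,
                  ) -> dict[str, EvalReport]:
    """Run a roster of reference classifiers through the identical pipeline.

    Unavailable roster entries (missing optional dependency) are skipped
    with a logged warning.
    """
    from .baselines import default_roster
    roster = roster if roster is not None else default_roster()
    reports = {}
    for name, fn in roster.items():
        if fn is None:
            logger.warning("baseline %s unavailable in this environment; "
                           "skipping", name)
            continue
        reports[name] = cross_validate(fn, cohort, K=plan.K, seed=plan.seed,
                                       model_name=name, plan=plan)
    return reports
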