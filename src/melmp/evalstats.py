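"""Evaluation protocol and enrichment statistics.

Stratified 10-fold cross-validation with support-weighted precision,
recall and F-score (the benchmark is imbalanced: many more verified
moonlighting proteins than screened negatives), pooled and per-fold
ROC/AUC, and the exact hypergeometric upper-tail enrichment test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import hypergeom
from sklearn.metrics import auc as _auc
from sklearn.metrics import precision_recall_fscore_support, roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import MelmpError
from .learners import LabeledDataset


@dataclass
class FoldPlan:
    """A stratified partition of ids into test folds."""

    assignments: dict[str, int]
    folds: int

    def test_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignments.items() if f == fold]


@dataclass
class EvalReport:
    """Per-fold and mean weighted metrics plus ROC/AUC."""

    fold_precision: list[float] = field(default_factory=list)
    fold_recall: list[float] = field(default_factory=list)
    fold_f: list[float] = field(default_factory=list)
    fold_auc: list[float] = field(default_factory=list)
    pooled_roc: tuple[np.ndarray, np.ndarray] | None = None
    pooled_auc: float = float("nan")

    @property
    def precision(self) -> float:
        return float(np.mean(self.fold_precision))

    @property
    def recall(self) -> float:
        return float(np.mean(self.fold_recall))

    @property
    def f_score(self) -> float:
        return float(np.mean(self.fold_f))

    @property
    def auc(self) -> float:
        return float(np.mean(self.fold_auc))

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "auc": self.auc,
            "pooled_auc": self.pooled_auc,
            "fold_precision": self.fold_precision,
            "fold_recall": self.fold_recall,
            "fold_f": self.fold_f,
            "fold_auc": self.fold_auc,
        }


def weighted_metrics(
    truth: np.ndarray, predicted: np.ndarray
) -> tuple[float, float, float]:
    """Support-weighted precision, recall and F-score.

    Per-class values are averaged with weights proportional to class
    support. A per-class value with a zero denominator is treated as 0
    (with a warning).
    """
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.size == 0:
        raise ValueError("empty input")
    if truth.shape != predicted.shape:
        raise ValueError("truth and predictions disagree in length")
    classes = np.union1d(np.unique(truth), np.unique(predicted))
    undefined = any(
        (predicted == c).sum() == 0 or (truth == c).sum() == 0 for c in classes
    )
    if undefined:
        warnings.warn(
            "some per-class metrics are undefined (zero denominator); "
            "treating them as 0",
            stacklevel=2,
        )
    p, r, f, _ = precision_recall_fscore_support(
        truth, predicted, average="weighted", zero_division=0
    )
    return float(p), float(r), float(f)


def roc_auc(
    truth: np.ndarray, probabilities: np.ndarray
) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC points (fpr, tpr) over the full threshold sweep and trapezoid AUC."""
    truth = np.asarray(truth, dtype=int)
    if len(np.unique(truth)) < 2:
        raise MelmpError("AUC undefined: only one class present")
    fpr, tpr, _ = roc_curve(truth, probabilities)
    return (fpr, tpr), float(_auc(fpr, tpr))


def make_folds(
    ids: list[str], labels: np.ndarray, folds: int = 10, seed: int = 0
) -> FoldPlan:
    """Stratified fold plan; every id tests exactly once."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels)
    if counts.min() < folds:
        raise MelmpError(
            f"need at least {folds} examples per class for {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignments: dict[str, int] = {}
    for fold, (_, te_idx) in enumerate(skf.split(np.zeros(len(ids)), labels)):
        for i in te_idx:
            assignments[ids[i]] = fold
    return FoldPlan(assignments=assignments, folds=folds)


def run_cv(
    data: LabeledDataset,
    pipeline_factory: Callable[[], object],
    folds: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Cross-validate a pipeline.

    ``pipeline_factory()`` must return a fresh estimator with
    ``fit(LabeledDataset)`` and ``predict_proba(views_dict) -> proba``;
    each fold's estimator is trained without that fold's test rows
    (any inner meta-feature construction happens inside ``fit`` on the
    training subset only).
    """
    plan = make_folds(data.ids, data.labels, folds=folds, seed=seed)
    id_index = {pid: i for i, pid in enumerate(data.ids)}
    report = EvalReport()
    pooled_truth: list[np.ndarray] = []
    pooled_proba: list[np.ndarray] = []
    for fold in range(folds):
        te_ids = plan.test_ids(fold)
        te_idx = np.array([id_index[i] for i in te_ids])
        tr_idx = np.array([i for i in range(len(data)) if i not in set(te_idx)])
        pipe = pipeline_factory()
        pipe.fit(data.subset(tr_idx))
        proba = np.asarray(
            pipe.predict_proba({v: m[te_idx] for v, m in data.views.items()})
        )
        pred = (proba >= 0.5).astype(int)
        truth = data.labels[te_idx]
        p, r, f = weighted_metrics(truth, pred)
        report.fold_precision.append(p)
        report.fold_recall.append(r)
        report.fold_f.append(f)
        if len(np.unique(truth)) == 2:
            _, fold_auc = roc_auc(truth, proba)
            report.fold_auc.append(fold_auc)
        pooled_truth.append(truth)
        pooled_proba.append(proba)
    truth_all = np.concatenate(pooled_truth)
    proba_all = np.concatenate(pooled_proba)
    report.pooled_roc, report.pooled_auc = roc_auc(truth_all, proba_all)
    return report


# ---------------------------------------------------------------------------
# hypergeometric enrichment


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts of the hypergeometric enrichment test.

    N proteins in the population, M of them in the category of interest,
    n drawn (e.g. disease-mapped), m of the drawn in the category.
    """

    N: int
    n: int
    M: int
    m: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.m <= min(self.n, self.M)
            and self.M <= self.N
            and self.n <= self.N
        )
        if not ok:
            raise ValueError(
                f"invalid enrichment counts N={self.N}, n={self.n}, "
                f"M={self.M}, m={self.m}"
            )


def hypergeom_enrich(inp: EnrichmentInput, tail: str = "ge") -> float:
    """Exact hypergeometric tail probability of the observed overlap.

    ``tail='ge'`` gives the standard enrichment P(X >= m) = 1 - CDF(m-1);
    ``tail='gt'`` gives the strictly-exceeding tail P(X > m) = 1 - CDF(m).
    The strict variant is the convention that reproduces this package's
    reference disease-association values (see docs/methods.md).
    """
    if tail == "ge":
        k = inp.m - 1
    elif tail == "gt":
        k = inp.m
    else:
        raise ValueError("tail must be 'ge' or 'gt'")
    # survival function is computed stably in log space internally
    return float(hypergeom.sf(k, inp.N, inp.M, inp.n))
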