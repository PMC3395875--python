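"""Cross-validated evaluation and strategy comparison.

Sites are partitioned into k (default 10) label-stratified folds; a
meta-predictor is evaluated by pooling its test-fold predictions over all
rotations so every site is predicted exactly once, and Sn/Sp/ACC/MCC (plus
AUC from the pooled continuous voting scores) are computed on the pool.

Weight updates follow a hill-climbing acceptance rule: a candidate weight
vector replaces the incumbent only if its pooled-CV MCC strictly increases
and its pooled-CV ACC does not decrease; otherwise the incumbent is kept
(rolled back). The trajectory of accepted (MCC, ACC) pairs is therefore
non-decreasing in MCC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .metrics import PerformanceReport, RocCurve, evaluate_binary, performance, \
    confusion_counts, roc_curve
from .voting import MetaPredictor, PredictionMatrix, _extract_X

__all__ = [
    "FoldAssignment",
    "ComparisonReport",
    "make_folds",
    "pooled_cv_report",
    "cv_hill_climb",
    "evaluate_elements",
    "compare_strategies",
]


@dataclass(frozen=True)
class FoldAssignment:
    """A k-fold partition of sites: fold index per site, with its seed."""

    fold_of: np.ndarray
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        f = np.asarray(self.fold_of, dtype=int)
        if set(np.unique(f)) != set(range(self.n_folds)):
            raise ValueError("fold indices must cover 0..n_folds-1")
        object.__setattr__(self, "fold_of", f)

    @property
    def n_sites(self) -> int:
        return self.fold_of.size

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def make_folds(labels, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Reproducible label-stratified k-fold partition.

    Stratification keeps each fold's class balance close to the global one,
    the finite-sample analogue of evaluating on a globally balanced dataset.
    Fold sizes differ by at most one site.
    """
    y = np.asarray(labels)
    if y.size < n_folds:
        raise ValueError(f"need at least {n_folds} sites, got {y.size}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_of = np.empty(y.size, dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        fold_of[test_idx] = f
    return FoldAssignment(fold_of=fold_of, n_folds=n_folds, seed=seed)


def pooled_cv_report(meta: MetaPredictor, matrix, labels,
                     folds: FoldAssignment) -> PerformanceReport:
    """Pooled test-fold performance of a fixed meta-predictor.

    The test fold rotates stepwise over all k folds; predictions on each
    test fold are pooled and scored once, so the pooled confusion counts sum
    to the number of sites.
    """
    calls, _ = _extract_X(matrix)
    y = np.asarray(labels)
    preds = np.empty(y.size, dtype=np.int8)
    scores = np.empty(y.size, dtype=float)
    for f in range(folds.n_folds):
        idx = folds.test_indices(f)
        scores[idx] = meta.score(calls[idx])
        preds[idx] = meta.predict(calls[idx])
    auc = roc_curve(scores, y).area if 0 < y.sum() < y.size else None
    return performance(confusion_counts(preds, y), auc=auc,
                       name=meta.strategy_tag)


def cv_hill_climb(matrix, labels, folds: FoldAssignment,
                  proposal_source: Iterable, init: MetaPredictor,
                  ) -> tuple[MetaPredictor, PerformanceReport]:
    """Hill-climb over candidate weight/threshold proposals under pooled CV.

    Candidates come from ``proposal_source`` (MetaPredictor instances or
    (weights, threshold) pairs). A candidate is kept only if its pooled-CV
    MCC strictly increases and its ACC does not decrease; otherwise the
    weights roll back to the incumbent. An empty stream returns ``init``.
    """
    incumbent = init
    inc_report = pooled_cv_report(init, matrix, labels, folds)
    for cand in proposal_source:
        if not isinstance(cand, MetaPredictor):
            w, t = cand
            cand = MetaPredictor(weights=np.asarray(w, dtype=float),
                                 threshold=float(t), strategy_tag="hill-climb")
        rep = pooled_cv_report(cand, matrix, labels, folds)
        if rep.mcc > inc_report.mcc and rep.acc >= inc_report.acc:
            incumbent, inc_report = cand, rep
    return incumbent, inc_report


def evaluate_elements(matrix, labels) -> list[PerformanceReport]:
    """Benchmark every element predictor column, in input column order."""
    calls, names = _extract_X(matrix)
    y = np.asarray(labels)
    reports = []
    for j in range(calls.shape[1]):
        name = names[j] if names else f"predictor_{j}"
        auc = (roc_curve(calls[:, j].astype(float), y).area
               if 0 < y.sum() < y.size else None)
        rep = evaluate_binary(calls[:, j], y, name=name)
        reports.append(PerformanceReport(sn=rep.sn, sp=rep.sp, acc=rep.acc,
                                         mcc=rep.mcc, auc=auc, name=name))
    return reports


@dataclass
class ComparisonReport:
    """Per-strategy ACC/MCC/AUC rows next to the best-element baseline."""

    rows: list[PerformanceReport]
    best_element: PerformanceReport
    roc_curves: dict[str, RocCurve] = field(default_factory=dict)
    models: dict[str, MetaPredictor] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        records = [self.best_element.as_dict()] + [r.as_dict() for r in self.rows]
        return pd.DataFrame.from_records(records)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "best_element": self.best_element.as_dict(),
                "strategies": [r.as_dict() for r in self.rows],
            },
            indent=2,
        )


def compare_strategies(matrix, labels, folds: FoldAssignment,
                       strategies: Mapping[str, object]) -> ComparisonReport:
    """Run each strategy under one shared fold assignment and tabulate results.

    Each strategy is a scikit-learn-style voting classifier; it is refit on
    the training folds of every rotation and its test-fold calls and
    continuous voting scores are pooled. ACC/MCC come from the pooled binary
    calls, AUC from the ROC of the pooled scores. The baseline row is the
    element predictor with the highest MCC on the same sites.
    """
    calls, names = _extract_X(matrix)
    y = np.asarray(labels)

    element_reports = evaluate_elements(matrix, labels)
    best_elem = max(element_reports, key=lambda r: r.mcc)
    best_elem = PerformanceReport(
        sn=best_elem.sn, sp=best_elem.sp, acc=best_elem.acc, mcc=best_elem.mcc,
        auc=best_elem.auc, name=f"best element ({best_elem.name})",
    )

    rows: list[PerformanceReport] = []
    curves: dict[str, RocCurve] = {}
    models: dict[str, MetaPredictor] = {}
    for name, proto in strategies.items():
        preds = np.empty(y.size, dtype=np.int8)
        scores = np.empty(y.size, dtype=float)
        for f in range(folds.n_folds):
            tr, te = folds.train_indices(f), folds.test_indices(f)
            est = clone(proto)
            est.fit(calls[tr], y[tr])
            scores[te] = est.decision_function(calls[te])
            preds[te] = est.predict(calls[te])
        curve = roc_curve(scores, y)
        rep = evaluate_binary(preds, y, name=name)
        rows.append(PerformanceReport(sn=rep.sn, sp=rep.sp, acc=rep.acc,
                                      mcc=rep.mcc, auc=curve.area, name=name))
        curves[name] = curve
        # also keep a full-data fit for downstream prediction
        full = clone(proto).fit(calls, y)
        models[name] = full.to_meta_predictor()
    return ComparisonReport(rows=rows, best_element=best_elem,
                            roc_curves=curves, models=models)
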