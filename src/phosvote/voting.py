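"""Linear weighted-voting meta-classifiers over binary predictor calls.

A meta-predictor combines the binary calls P_j of N element predictors into
one call per site: the site is positive iff

    sum_j P_j * w_j  >=  T

with non-negative weights w_j and threshold T. The tie at score == T is
positive. For a plain weighted vote the canonical threshold is half the
total weight, T = (sum_j w_j) / 2.

Three constructive strategies are provided as scikit-learn estimators:

* :class:`UnweightedVotingClassifier` — all weights 1 (majority vote).
* :class:`MetricWeightedVotingClassifier` — w_j set to predictor j's ACC or
  MCC measured on the training data (MCC floored at 0, since votes are
  non-negative).
* :class:`ReducedVotingClassifier` — metric-weighted vote over the best
  rank-prefix subset of predictors.

The lattice-constrained grid search and its randomized refinement live in
:mod:`phosvote.search`. Module-level ``build_*`` functions are thin wrappers
returning a plain :class:`MetaPredictor` record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .metrics import evaluate_binary

__all__ = [
    "PredictionMatrix",
    "MetaPredictor",
    "BaseVotingClassifier",
    "UnweightedVotingClassifier",
    "MetricWeightedVotingClassifier",
    "ReducedVotingClassifier",
    "meta_predict",
    "half_weight_threshold",
    "build_unweighted",
    "build_weighted_by_metric",
    "reduce_predictors",
    "read_labels",
    "write_labels",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class PredictionMatrix:
    """Binary calls of N element predictors on n candidate sites.

    Rows are sites (identified by unique ``site_ids``), columns are element
    predictors; every entry is 0 or 1. Real-valued element scores are never
    stored: each element predictor is reduced to its binary call.
    """

    site_ids: tuple[str, ...]
    calls: np.ndarray
    predictor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls)
        if calls.ndim != 2:
            raise ValueError(f"calls must be 2-D, got shape {calls.shape}")
        n, m = calls.shape
        if m < 1:
            raise ValueError("at least one predictor column required")
        if len(self.site_ids) != n:
            raise ValueError("site_ids length must match number of rows")
        if len(self.predictor_names) != m:
            raise ValueError("predictor_names length must match number of columns")
        if len(set(self.site_ids)) != n:
            raise ValueError("duplicate site_ids")
        if len(set(self.predictor_names)) != m:
            raise ValueError("duplicate predictor names")
        uniq = np.unique(calls)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError(f"calls must be binary, found values {uniq}")
        object.__setattr__(self, "calls", calls.astype(np.int8))
        object.__setattr__(self, "site_ids", tuple(str(s) for s in self.site_ids))
        object.__setattr__(
            self, "predictor_names", tuple(str(s) for s in self.predictor_names)
        )

    @property
    def n_sites(self) -> int:
        return self.calls.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.calls.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.calls[:, self.predictor_names.index(name)]

    def reorder(self, names: Sequence[str]) -> "PredictionMatrix":
        """Reorder/select predictor columns by name (missing name -> KeyError)."""
        missing = [n for n in names if n not in self.predictor_names]
        if missing:
            raise KeyError(f"predictor column(s) not in matrix: {missing}")
        idx = [self.predictor_names.index(n) for n in names]
        return PredictionMatrix(self.site_ids, self.calls[:, idx], tuple(names))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.calls, columns=list(self.predictor_names))
        df.insert(0, "site_id", list(self.site_ids))
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PredictionMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
        if df.columns[0] != "site_id":
            raise ValueError("first column of a prediction matrix must be 'site_id'")
        names = tuple(df.columns[1:])
        return cls(tuple(df["site_id"]), df[list(names)].to_numpy(), names)


def read_labels(path, site_ids: Sequence[str] | None = None) -> np.ndarray:
    """Read a site_id -> {0,1} label TSV; optionally align to a site order."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    if list(df.columns[:2]) != ["site_id", "label"]:
        raise ValueError("label file must have columns site_id, label")
    series = df.set_index("site_id")["label"]
    if site_ids is not None:
        missing = [s for s in site_ids if s not in series.index]
        if missing:
            raise KeyError(f"labels missing for site(s): {missing[:5]}")
        series = series.loc[list(site_ids)]
    labels = series.to_numpy()
    if not np.isin(np.unique(labels), [0, 1]).all():
        raise ValueError("labels must be 0/1")
    return labels.astype(np.int8)


def write_labels(path, site_ids: Sequence[str], labels) -> None:
    pd.DataFrame({"site_id": list(site_ids), "label": np.asarray(labels, dtype=int)}
                 ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class MetaPredictor:
    """A fitted weighted-voting rule: weights w, threshold T, and provenance."""

    weights: np.ndarray
    threshold: float
    strategy_tag: str = "custom"
    predictor_names: tuple[str, ...] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("weights must be a non-empty 1-D vector")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.predictor_names is not None and len(self.predictor_names) != w.size:
            raise ValueError("predictor_names length must match weights")
        object.__setattr__(self, "weights", w)

    @property
    def n_predictors(self) -> int:
        return self.weights.size

    def _calls_of(self, matrix) -> np.ndarray:
        if isinstance(matrix, PredictionMatrix):
            if (self.predictor_names is not None
                    and matrix.predictor_names != self.predictor_names):
                matrix = matrix.reorder(self.predictor_names)
            calls = matrix.calls
        else:
            calls = np.asarray(matrix)
        if calls.ndim != 2 or calls.shape[1] != self.n_predictors:
            raise ValueError(
                f"matrix has {calls.shape[1] if calls.ndim == 2 else '?'} predictors, "
                f"model expects {self.n_predictors}"
            )
        return calls

    def score(self, matrix) -> np.ndarray:
        """Continuous voting score sum_j P_j w_j per site."""
        return self._calls_of(matrix).astype(float) @ self.weights

    def predict(self, matrix) -> np.ndarray:
        """Binary call per site: 1 iff score >= threshold."""
        return (self.score(matrix) >= self.threshold).astype(np.int8)

    def to_json(self) -> str:
        return json.dumps(
            {
                "predictor_names": list(self.predictor_names)
                if self.predictor_names else None,
                "weights": [float(w) for w in self.weights],
                "threshold": float(self.threshold),
                "strategy_tag": self.strategy_tag,
                "provenance": self.provenance,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MetaPredictor":
        d = json.loads(text)
        names = d.get("predictor_names")
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            threshold=float(d["threshold"]),
            strategy_tag=d.get("strategy_tag", "custom"),
            predictor_names=tuple(names) if names else None,
            provenance=d.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# estimators


def _extract_X(X) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(X, PredictionMatrix):
        return X.calls, X.predictor_names
    arr = np.asarray(X)
    if arr.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {arr.shape}")
    uniq = np.unique(arr)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError(f"element calls must be binary, found values {uniq}")
    return arr.astype(np.int8), None


def half_weight_threshold(weights) -> float:
    """Canonical voting threshold: half the total weight, T = (sum_j w_j)/2."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    return float(w.sum() / 2.0)


class BaseVotingClassifier(ClassifierMixin, BaseEstimator):
    """Shared predict/decision plumbing for fitted weighted-vote classifiers.

    Subclasses set ``weights_`` and ``threshold_`` in ``fit``.
    """

    strategy_tag = "custom"

    def _finish_fit(self, X, names) -> "BaseVotingClassifier":
        self.n_features_in_ = self.weights_.size
        self.classes_ = np.array([0, 1])
        self.predictor_names_ = names
        return self

    def decision_function(self, X) -> np.ndarray:
        calls, _ = _extract_X(X)
        if calls.shape[1] != self.weights_.size:
            raise ValueError(
                f"X has {calls.shape[1]} predictors, model expects {self.weights_.size}"
            )
        return calls.astype(float) @ self.weights_

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= self.threshold_).astype(np.int8)

    def to_meta_predictor(self) -> MetaPredictor:
        return MetaPredictor(
            weights=self.weights_.copy(),
            threshold=float(self.threshold_),
            strategy_tag=self.strategy_tag,
            predictor_names=self.predictor_names_,
            provenance=getattr(self, "provenance_", {}),
        )


class UnweightedVotingClassifier(BaseVotingClassifier):
    """Majority vote: every element predictor has weight 1.

    Parameters
    ----------
    threshold : float, optional
        Overrides the default T = N/2 (half the total weight).
    """

    strategy_tag = "unweighted"

    def __init__(self, threshold: float | None = None):
        self.threshold = threshold

    def fit(self, X, y=None):
        calls, names = _extract_X(X)
        self.weights_ = np.ones(calls.shape[1])
        self.threshold_ = (half_weight_threshold(self.weights_)
                          if self.threshold is None else float(self.threshold))
        return self._finish_fit(X, names)


class MetricWeightedVotingClassifier(BaseVotingClassifier):
    """Weighted vote with w_j = predictor j's ACC or MCC on the training data.

    MCC weights are floored at 0 because the vote assumes non-negative
    weights; a predictor whose metric is undefined gets weight 0.
    """

    def __init__(self, metric: str = "acc", threshold: float | None = None):
        self.metric = metric
        self.threshold = threshold

    @property
    def strategy_tag(self) -> str:  # type: ignore[override]
        return f"weighted-{self.metric}"

    def fit(self, X, y):
        if self.metric not in ("acc", "mcc"):
            raise ValueError(f"metric must be 'acc' or 'mcc', got {self.metric!r}")
        calls, names = _extract_X(X)
        y = np.asarray(y)
        if y.shape[0] != calls.shape[0]:
            raise ValueError("X and y have different numbers of sites")
        self.weights_ = per_predictor_metric(calls, y, self.metric)
        self.threshold_ = (half_weight_threshold(self.weights_)
                          if self.threshold is None else float(self.threshold))
        return self._finish_fit(X, names)


class ReducedVotingClassifier(BaseVotingClassifier):
    """Metric-weighted vote over a selected rank-prefix subset of predictors.

    Predictors are ranked by ``metric`` (descending, stable); for each prefix
    top-k (k = 1..N) a metric-weighted half-threshold vote restricted to that
    prefix is evaluated on the training data, and the prefix maximizing the
    ``objective`` MCC is kept (ties: higher ACC, then smaller k). Excluded
    predictors keep weight 0, so the fitted model still consumes full-width
    call matrices.
    """

    def __init__(self, metric: str = "mcc", objective: str = "mcc",
                 threshold: float | None = None):
        self.metric = metric
        self.objective = objective
        self.threshold = threshold

    @property
    def strategy_tag(self) -> str:  # type: ignore[override]
        return f"reduced-{self.metric}"

    def fit(self, X, y):
        calls, names = _extract_X(X)
        y = np.asarray(y)
        metric_vals = per_predictor_metric(calls, y, self.metric)
        order = np.argsort(-metric_vals, kind="stable")
        best_key, best_k, best_w, best_t = None, None, None, None
        for k in range(1, calls.shape[1] + 1):
            sel = order[:k]
            w = np.zeros(calls.shape[1])
            w[sel] = metric_vals[sel]
            t = (half_weight_threshold(w) if self.threshold is None
                 else float(self.threshold))
            rep = evaluate_binary(
                (calls.astype(float) @ w >= t).astype(int), y
            )
            key = (rep.mcc, rep.acc, -k)  # maximize mcc, then acc, then prefer small k
            if best_key is None or key > best_key:
                best_key, best_k, best_w, best_t = key, k, w, t
        self.weights_ = best_w
        self.threshold_ = best_t
        self.support_ = np.sort(order[:best_k])
        self.n_selected_ = best_k
        return self._finish_fit(X, names)


def per_predictor_metric(calls: np.ndarray, y: np.ndarray, metric: str) -> np.ndarray:
    """ACC or MCC of each call column against y; MCC floored at 0."""
    vals = np.empty(calls.shape[1])
    for j in range(calls.shape[1]):
        rep = evaluate_binary(calls[:, j], y)
        vals[j] = rep.acc if metric == "acc" else max(rep.mcc, 0.0)
    return vals


# ---------------------------------------------------------------------------
# functional wrappers


def meta_predict(matrix, meta: MetaPredictor) -> np.ndarray:
    """Apply a meta-predictor to a call matrix: positive iff sum P_j w_j >= T."""
    return meta.predict(matrix)


def build_unweighted(matrix, threshold_override: float | None = None) -> MetaPredictor:
    clf = UnweightedVotingClassifier(threshold=threshold_override).fit(matrix)
    return clf.to_meta_predictor()


def build_weighted_by_metric(matrix, labels, metric: str = "acc",
                             threshold_override: float | None = None) -> MetaPredictor:
    clf = MetricWeightedVotingClassifier(
        metric=metric.lower(), threshold=threshold_override
    ).fit(matrix, labels)
    return clf.to_meta_predictor()


def reduce_predictors(matrix, labels, metric: str = "mcc", objective: str = "mcc",
                      ) -> tuple[np.ndarray, MetaPredictor]:
    """Rank-prefix predictor reduction; returns (selected indices, model)."""
    clf = ReducedVotingClassifier(metric=metric.lower(),
                                  objective=objective.lower()).fit(matrix, labels)
    return clf.support_, clf.to_meta_predictor()
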