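"""Weight selection for the voting meta-classifier.

Two schemes are implemented:

**Restricted grid search** exhaustively evaluates every weight vector on a
constrained lattice — each w_j drawn from a small allowed set (default
{0, 1, 3, 5, 7, 9, 11, 13, 15}) with the total sum fixed (default 15) —
jointly with every candidate threshold T (default the integers
0..weight_sum). The (w, T) pair with the highest MCC wins; ties break by
higher ACC, then the lexicographically smallest weight vector, then the
smallest T, so results are deterministic.

**Conditional random search** refines the grid optimum: each weight is
redrawn uniformly from the interval bracketing its grid value (between the
previous and the next lattice point), the threshold is a uniform fraction of
the new total weight, and drawing stops at the first candidate that strictly
beats the grid-search MCC (or after ``max_iter`` draws, returning the best
seen). The grid solution seeds the incumbent, so the refined result is never
worse than the grid result.

Candidate evaluation is vectorized: a block of weight vectors is scored
against all sites in one matrix product and confusion counts are reduced
per threshold, which makes the full default lattice (~2.6M compositions
x 16 thresholds) tractable and small lattices instantaneous.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np

from .voting import (
    BaseVotingClassifier,
    MetaPredictor,
    PredictionMatrix,
    _extract_X,
)

__all__ = [
    "GridSpec",
    "SearchResult",
    "RandomRange",
    "enumerate_compositions",
    "count_assignments",
    "total_assignments",
    "iter_partitions",
    "random_range",
    "restricted_grid_search",
    "conditional_random_search",
    "RestrictedGridSearchClassifier",
    "ConditionalRandomSearchClassifier",
]

DEFAULT_ALLOWED_WEIGHTS = (0, 1, 3, 5, 7, 9, 11, 13, 15)
DEFAULT_WEIGHT_SUM = 15


@dataclass(frozen=True)
class GridSpec:
    """The restricted-grid lattice: allowed weights, fixed sum, T candidates."""

    allowed_weights: tuple[int, ...] = DEFAULT_ALLOWED_WEIGHTS
    weight_sum: int = DEFAULT_WEIGHT_SUM
    n_predictors: int = 15
    t_candidates: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        aw = tuple(sorted(int(w) for w in self.allowed_weights))
        if len(set(aw)) != len(aw):
            raise ValueError("allowed_weights must be distinct")
        if 0 not in aw:
            raise ValueError("allowed_weights must contain 0")
        if any(w < 0 for w in aw):
            raise ValueError("allowed_weights must be non-negative")
        if self.weight_sum <= 0:
            raise ValueError("weight_sum must be positive")
        if self.n_predictors < 1:
            raise ValueError("n_predictors must be >= 1")
        object.__setattr__(self, "allowed_weights", aw)
        if self.t_candidates is None:
            object.__setattr__(
                self, "t_candidates", tuple(float(t) for t in range(self.weight_sum + 1))
            )
        else:
            object.__setattr__(
                self, "t_candidates", tuple(float(t) for t in self.t_candidates)
            )

    def as_dict(self) -> dict:
        return {
            "allowed_weights": list(self.allowed_weights),
            "weight_sum": self.weight_sum,
            "n_predictors": self.n_predictors,
            "t_candidates": list(self.t_candidates),
        }


@dataclass(frozen=True)
class RandomRange:
    """Half-open interval [lo, hi) from which a refined weight is drawn."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"empty range [{self.lo}, {self.hi})")


@dataclass
class SearchResult:
    """Outcome of a weight search: the best model and how it was found."""

    best: MetaPredictor
    best_mcc: float
    best_acc: float
    n_evaluated: int
    spec: GridSpec | None = None
    converged: bool | None = None
    trace: list = field(default_factory=list)

    def as_dict(self) -> dict:
        import json

        return {
            "best": json.loads(self.best.to_json()),
            "best_mcc": self.best_mcc,
            "best_acc": self.best_acc,
            "n_evaluated": self.n_evaluated,
            "spec": self.spec.as_dict() if self.spec else None,
            "converged": self.converged,
            "trace": self.trace,
        }


# ---------------------------------------------------------------------------
# lattice combinatorics


def _feasible_sums(allowed: tuple[int, ...], n_slots: int, cap: int) -> list[set]:
    """feasible[r] = set of sums reachable with r slots (sums capped at cap)."""
    feasible = [set() for _ in range(n_slots + 1)]
    feasible[0] = {0}
    for r in range(1, n_slots + 1):
        reach = set()
        for s in feasible[r - 1]:
            for w in allowed:
                t = s + w
                if t <= cap:
                    reach.add(t)
        feasible[r] = reach
    return feasible


def enumerate_compositions(spec: GridSpec) -> Iterator[tuple[int, ...]]:
    """Yield every weight vector on the lattice, in lexicographic order.

    A vector qualifies iff every entry is an allowed weight and the entries
    sum to ``spec.weight_sum``; each qualifying vector is yielded exactly
    once. An infeasible spec yields nothing.
    """
    allowed = spec.allowed_weights
    n = spec.n_predictors
    target = spec.weight_sum
    feasible = _feasible_sums(allowed, n, target)

    def rec(prefix: list[int], remaining_sum: int, slots_left: int):
        if slots_left == 0:
            if remaining_sum == 0:
                yield tuple(prefix)
            return
        for w in allowed:
            rest = remaining_sum - w
            if rest < 0:
                continue
            if rest not in feasible[slots_left - 1]:
                continue
            prefix.append(w)
            yield from rec(prefix, rest, slots_left - 1)
            prefix.pop()

    yield from rec([], target, n)


def count_assignments(parts: Sequence[int], n_predictors: int) -> int:
    """Number of distinct weight vectors realizing a nonzero-part multiset.

    ``parts`` lists the nonzero weights (with repetition); the remaining
    ``n_predictors - len(parts)`` predictors receive weight 0. Predictors are
    distinguishable, so the count is the multinomial coefficient
    n! / (m_0! * prod_v m_v!) over the multiplicities of each distinct value.
    """
    parts = list(parts)
    if any(p <= 0 for p in parts):
        raise ValueError("parts must be positive")
    if len(parts) > n_predictors:
        raise ValueError("more parts than predictors")
    mult = Counter(parts)
    denom = math.factorial(n_predictors - len(parts))
    for m in mult.values():
        denom *= math.factorial(m)
    return math.factorial(n_predictors) // denom


def iter_partitions(total: int, allowed_nonzero: Sequence[int],
                    max_parts: int) -> Iterator[tuple[int, ...]]:
    """Partitions of ``total`` into at most ``max_parts`` parts from the set."""
    vals = sorted(set(int(v) for v in allowed_nonzero), reverse=True)

    def rec(remaining: int, parts: list[int], start: int):
        if remaining == 0:
            yield tuple(parts)
            return
        if len(parts) == max_parts:
            return
        for i in range(start, len(vals)):
            v = vals[i]
            if v <= remaining:
                parts.append(v)
                yield from rec(remaining - v, parts, i)
                parts.pop()

    yield from rec(total, [], 0)


def total_assignments(spec: GridSpec) -> int:
    """Analytic size of the grid: sum of multinomial counts over partitions."""
    nonzero = [w for w in spec.allowed_weights if w > 0]
    return sum(
        count_assignments(parts, spec.n_predictors)
        for parts in iter_partitions(spec.weight_sum, nonzero, spec.n_predictors)
    )


def random_range(grid_value: int, spec: GridSpec) -> RandomRange:
    """Refinement interval bracketing a lattice value.

    [lo, hi) spans from the previous allowed weight to the next one; the
    smallest lattice value is bracketed below by 0 and the largest above by
    itself + 2 (one lattice spacing beyond the end).
    """
    allowed = spec.allowed_weights
    if grid_value not in allowed:
        raise ValueError(f"{grid_value} is not on the lattice {allowed}")
    i = allowed.index(grid_value)
    lo = float(allowed[i - 1]) if i > 0 else 0.0
    hi = float(allowed[i + 1]) if i + 1 < len(allowed) else float(allowed[-1] + 2)
    return RandomRange(lo=lo, hi=hi)


# ---------------------------------------------------------------------------
# vectorized candidate evaluation


def _score_candidates(W: np.ndarray, X: np.ndarray, y: np.ndarray,
                      t_candidates: Sequence[float]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """MCC and ACC of each (weight row, threshold) pair.

    Returns arrays of shape (n_candidates, n_thresholds); entry [i, t] scores
    the vote with weights W[i] at threshold t_candidates[t]. Zero-denominator
    MCC is 0.
    """
    y = np.asarray(y).astype(bool)
    n = y.size
    n_pos = int(y.sum())
    n_neg = n - n_pos
    scores = X.astype(np.float64) @ W.T  # (n_sites, n_candidates)
    pos_scores = scores[y]
    neg_scores = scores[~y]
    mcc = np.empty((W.shape[0], len(t_candidates)))
    acc = np.empty_like(mcc)
    for ti, t in enumerate(t_candidates):
        tp = (pos_scores >= t).sum(axis=0).astype(np.float64)
        fp = (neg_scores >= t).sum(axis=0).astype(np.float64)
        fn = n_pos - tp
        tn = n_neg - fp
        pp = tp + fp
        pn = fn + tn
        denom = np.sqrt(float(n_pos) * float(n_neg) * pp * pn)
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.where(denom > 0, (tp * tn - fn * fp) / denom, 0.0)
        mcc[:, ti] = m
        acc[:, ti] = (tp + tn) / n
    return mcc, acc


def _best_flat(mcc: np.ndarray, acc: np.ndarray) -> tuple[int, int, float, float]:
    """First (row, col) maximizing (mcc, acc) in row-major order."""
    flat_mcc = mcc.ravel()
    flat_acc = acc.ravel()
    top = np.flatnonzero(flat_mcc == flat_mcc.max())
    top = top[flat_acc[top] == flat_acc[top].max()]
    i = int(top[0])
    r, c = divmod(i, mcc.shape[1])
    return r, c, float(flat_mcc[i]), float(flat_acc[i])


# ---------------------------------------------------------------------------
# estimators


class RestrictedGridSearchClassifier(BaseVotingClassifier):
    """Weighted-vote classifier fitted by exhaustive lattice search.

    Parameters
    ----------
    allowed_weights : sequence of int
        The lattice each weight is drawn from; must contain 0.
    weight_sum : int
        Required total of all weights.
    t_candidates : sequence of float, optional
        Threshold grid; defaults to the integers 0..weight_sum (with integer
        weights and the >= decision rule, intermediate thresholds are
        redundant).
    objective : {'mcc', 'acc'}
        Primary selection criterion; the other measure breaks ties, then the
        lexicographically smallest weight vector, then the smallest T.
    chunk_size : int
        Number of weight vectors scored per matrix product.
    """

    strategy_tag = "grid-search"

    def __init__(self, allowed_weights=DEFAULT_ALLOWED_WEIGHTS,
                 weight_sum=DEFAULT_WEIGHT_SUM, t_candidates=None,
                 objective: str = "mcc", chunk_size: int = 8192):
        self.allowed_weights = allowed_weights
        self.weight_sum = weight_sum
        self.t_candidates = t_candidates
        self.objective = objective
        self.chunk_size = chunk_size

    def _spec(self, n_predictors: int) -> GridSpec:
        return GridSpec(
            allowed_weights=tuple(self.allowed_weights),
            weight_sum=int(self.weight_sum),
            n_predictors=n_predictors,
            t_candidates=tuple(self.t_candidates) if self.t_candidates is not None
            else None,
        )

    def fit(self, X, y):
        if self.objective not in ("mcc", "acc"):
            raise ValueError("objective must be 'mcc' or 'acc'")
        calls, names = _extract_X(X)
        y = np.asarray(y)
        if y.shape[0] != calls.shape[0]:
            raise ValueError("X and y have different numbers of sites")
        spec = self._spec(calls.shape[1])
        t_cand = spec.t_candidates

        best = None  # (primary, secondary, weights, t)
        n_comps = 0
        chunk: list[tuple[int, ...]] = []

        def flush(chunk_rows):
            nonlocal best
            W = np.asarray(chunk_rows, dtype=np.float64)
            mcc, acc = _score_candidates(W, calls, y, t_cand)
            if self.objective == "acc":
                mcc, acc = acc, mcc
            r, c, pri, sec = _best_flat(mcc, acc)
            # chunks arrive in lexicographic order, so strict comparison keeps
            # the lexicographically-smallest weights / smallest T among ties
            if best is None or (pri, sec) > (best[0], best[1]):
                best = (pri, sec, tuple(chunk_rows[r]), t_cand[c])

        for comp in enumerate_compositions(spec):
            chunk.append(comp)
            n_comps += 1
            if len(chunk) >= self.chunk_size:
                flush(chunk)
                chunk = []
        if chunk:
            flush(chunk)
        if best is None:
            raise ValueError(
                f"infeasible grid: no weight vector on {spec.allowed_weights} "
                f"of length {spec.n_predictors} sums to {spec.weight_sum}"
            )

        pri, sec, w, t = best
        self.weights_ = np.asarray(w, dtype=float)
        self.threshold_ = float(t)
        if self.objective == "acc":
            self.best_acc_, self.best_mcc_ = pri, sec
        else:
            self.best_mcc_, self.best_acc_ = pri, sec
        self.n_evaluated_ = n_comps * len(t_cand)
        self.spec_ = spec
        self.provenance_ = {"objective": self.objective, "spec": spec.as_dict()}
        return self._finish_fit(X, names)

    def to_search_result(self) -> SearchResult:
        return SearchResult(
            best=self.to_meta_predictor(),
            best_mcc=self.best_mcc_,
            best_acc=self.best_acc_,
            n_evaluated=self.n_evaluated_,
            spec=self.spec_,
        )


class ConditionalRandomSearchClassifier(BaseVotingClassifier):
    """Randomized refinement of a restricted-grid-search solution.

    Each draw redraws every weight uniformly from the interval bracketing its
    grid value on the lattice and sets T = u * sum(w) with u ~ Uniform[0, 1).
    The grid solution is the initial incumbent; a draw replaces it only if
    (MCC, ACC) improves, and drawing stops at the first draw whose MCC
    strictly exceeds the grid-search MCC, or after ``max_iter`` draws.

    Parameters
    ----------
    grid_result : SearchResult, optional
        A previously computed grid-search result; when omitted, fit runs
        :class:`RestrictedGridSearchClassifier` with the lattice parameters.
    max_iter : int
        Cap on the number of random draws (the stopping rule alone need not
        terminate).
    random_state : int
        Seed of the draw sequence; results are fully reproducible from it.
    """

    strategy_tag = "random-search"

    def __init__(self, allowed_weights=DEFAULT_ALLOWED_WEIGHTS,
                 weight_sum=DEFAULT_WEIGHT_SUM, t_candidates=None,
                 grid_result: SearchResult | None = None,
                 max_iter: int = 1000, random_state: int = 0):
        self.allowed_weights = allowed_weights
        self.weight_sum = weight_sum
        self.t_candidates = t_candidates
        self.grid_result = grid_result
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        if self.max_iter <= 0:
            raise ValueError("max_iter must be positive")
        calls, names = _extract_X(X)
        y = np.asarray(y)

        if self.grid_result is None:
            grid = RestrictedGridSearchClassifier(
                allowed_weights=self.allowed_weights, weight_sum=self.weight_sum,
                t_candidates=self.t_candidates,
            ).fit(calls, y)
            seed_result = grid.to_search_result()
        else:
            seed_result = self.grid_result
        spec = seed_result.spec or GridSpec(
            allowed_weights=tuple(self.allowed_weights),
            weight_sum=int(self.weight_sum), n_predictors=calls.shape[1],
            t_candidates=tuple(self.t_candidates) if self.t_candidates is not None
            else None,
        )

        grid_w = np.asarray(seed_result.best.weights)
        ranges = [random_range(int(round(w)), spec) for w in grid_w]
        lo = np.array([r.lo for r in ranges])
        hi = np.array([r.hi for r in ranges])
        grid_mcc = seed_result.best_mcc

        rng = np.random.default_rng(self.random_state)
        best_w = grid_w.astype(float)
        best_t = float(seed_result.best.threshold)
        best_mcc, best_acc = seed_result.best_mcc, seed_result.best_acc
        trace: list[dict] = []
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            w = rng.uniform(lo, hi)
            t = float(rng.uniform(0.0, 1.0) * w.sum())
            mcc, acc = _score_candidates(w[None, :], calls, y, [t])
            mcc, acc = float(mcc[0, 0]), float(acc[0, 0])
            if (mcc, acc) > (best_mcc, best_acc):
                best_w, best_t, best_mcc, best_acc = w, t, mcc, acc
                trace.append({"iteration": n_iter, "mcc": mcc, "acc": acc})
            if mcc > grid_mcc:
                converged = True
                break

        self.weights_ = np.asarray(best_w, dtype=float)
        self.threshold_ = best_t
        self.best_mcc_ = best_mcc
        self.best_acc_ = best_acc
        self.grid_mcc_ = grid_mcc
        self.converged_ = converged
        self.n_iterations_ = n_iter
        self.spec_ = spec
        self.trace_ = trace
        self.provenance_ = {
            "rng_seed": self.random_state,
            "max_iter": self.max_iter,
            "grid_mcc": grid_mcc,
            "converged": converged,
            "n_iterations": n_iter,
            "spec": spec.as_dict(),
        }
        return self._finish_fit(X, names)

    def to_search_result(self) -> SearchResult:
        return SearchResult(
            best=self.to_meta_predictor(),
            best_mcc=self.best_mcc_,
            best_acc=self.best_acc_,
            n_evaluated=self.n_iterations_,
            spec=self.spec_,
            converged=self.converged_,
            trace=self.trace_,
        )


# ---------------------------------------------------------------------------
# functional wrappers


def restricted_grid_search(matrix, labels, spec: GridSpec | None = None,
                           objective: str = "mcc") -> SearchResult:
    """Exhaustive lattice search; see :class:`RestrictedGridSearchClassifier`."""
    if spec is None:
        spec = GridSpec(n_predictors=_extract_X(matrix)[0].shape[1])
    clf = RestrictedGridSearchClassifier(
        allowed_weights=spec.allowed_weights, weight_sum=spec.weight_sum,
        t_candidates=spec.t_candidates, objective=objective,
    ).fit(matrix, labels)
    return clf.to_search_result()


def conditional_random_search(matrix, labels, seed_result: SearchResult,
                              spec: GridSpec | None = None, rng_seed: int = 0,
                              max_iter: int = 1000) -> SearchResult:
    """Randomized refinement; see :class:`ConditionalRandomSearchClassifier`."""
    if spec is None:
        spec = seed_result.spec
    if spec is None:
        raise ValueError("a GridSpec is required (in seed_result or explicitly)")
    clf = ConditionalRandomSearchClassifier(
        allowed_weights=spec.allowed_weights, weight_sum=spec.weight_sum,
        t_candidates=spec.t_candidates, grid_result=seed_result,
        max_iter=max_iter, random_state=rng_seed,
    ).fit(matrix, labels)
    return clf.to_search_result()
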