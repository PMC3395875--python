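"""Lattice enumeration/counting, grid search, and conditional random search."""

import itertools
from collections import Counter

import numpy as np
import pytest

from phosvote import (
    EnsembleSpec,
    GridSpec,
    conditional_random_search,
    count_assignments,
    enumerate_compositions,
    restricted_grid_search,
    simulate_ensemble,
    total_assignments,
)
from phosvote.metrics import evaluate_binary
from phosvote.search import RandomRange, iter_partitions, random_range
from phosvote.voting import PredictionMatrix


def matrix_of(calls):
    calls = np.asarray(calls)
    return PredictionMatrix(
        site_ids=tuple(f"s{i}" for i in range(calls.shape[0])),
        calls=calls,
        predictor_names=tuple(f"p{j}" for j in range(calls.shape[1])),
    )


class TestEnumeration:
    def test_small_case_exhaustive(self):
        spec = GridSpec(allowed_weights=(0, 1, 3), weight_sum=3, n_predictors=2)
        got = set(enumerate_compositions(spec))
        brute = {
            v for v in itertools.product((0, 1, 3), repeat=2) if sum(v) == 3
        }
        assert got == brute == {(0, 3), (3, 0)}

    def test_forced_single_vector(self):
        spec = GridSpec(allowed_weights=(0, 15), weight_sum=15, n_predictors=1)
        assert list(enumerate_compositions(spec)) == [(15,)]

    def test_infeasible_spec_is_empty(self):
        spec = GridSpec(allowed_weights=(0, 4), weight_sum=3, n_predictors=3)
        assert list(enumerate_compositions(spec)) == []

    def test_lexicographic_order_and_uniqueness(self):
        spec = GridSpec(allowed_weights=(0, 1, 3, 5), weight_sum=5,
                        n_predictors=4)
        vecs = list(enumerate_compositions(spec))
        assert vecs == sorted(set(vecs))

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_satisfies_both_restrictions_vs_brute_force(self, n):
        """Every yielded vector is on the lattice and sums right; none missing."""
        allowed = (0, 1, 3, 5, 7)
        spec = GridSpec(allowed_weights=allowed, weight_sum=7, n_predictors=n)
        got = list(enumerate_compositions(spec))
        brute = [v for v in itertools.product(allowed, repeat=n)
                 if sum(v) == 7]
        assert sorted(got) == sorted(brute)
        assert len(got) == len(set(got))


class TestCounting:
    @pytest.mark.parametrize(
        "parts, expected",
        [
            ([15], 15),
            ([1, 1, 13], 1365),
            ([1, 3, 11], 2730),
            ([1, 1, 1, 1, 11], 15015),
            ([1, 1, 1, 3, 9], 60060),
            ([1, 1, 1, 1, 1, 1, 9], 45045),
            ([1, 1, 3, 3, 7], 90090),
            ([1, 1, 1, 1, 1, 3, 7], 270270),
            ([1, 1, 1, 1, 3, 3, 5], 675675),
            ([1, 1, 1, 3, 3, 3, 3], 225225),
            ([1, 1, 1, 1, 1, 1, 3, 3, 3], 420420),
        ],
    )
    def test_multinomial_counts_n15(self, parts, expected):
        assert count_assignments(parts, 15) == expected

    def test_empty_parts(self):
        assert count_assignments([], 15) == 1

    def test_counts_match_enumeration_per_composition(self):
        """count_assignments equals the enumerated frequency of each multiset."""
        spec = GridSpec(allowed_weights=(0, 1, 3, 5), weight_sum=5,
                        n_predictors=6)
        freq = Counter(
            tuple(sorted(w for w in vec if w > 0))
            for vec in enumerate_compositions(spec)
        )
        for parts, n_seen in freq.items():
            assert count_assignments(list(parts), 6) == n_seen
        # and iter_partitions produces exactly the observed multisets
        parts_seen = set(freq)
        assert parts_seen == {
            tuple(sorted(p)) for p in iter_partitions(5, (1, 3, 5), 6)
        }

    def test_total_matches_enumeration_length(self):
        spec = GridSpec(allowed_weights=(0, 1, 3, 5, 7), weight_sum=7,
                        n_predictors=6)
        assert total_assignments(spec) == sum(
            1 for _ in enumerate_compositions(spec))

    def test_errors(self):
        with pytest.raises(ValueError):
            count_assignments([0, 1], 15)
        with pytest.raises(ValueError):
            count_assignments([1] * 16, 15)


class TestRandomRange:
    @pytest.mark.parametrize(
        "value, lo, hi",
        [(0, 0, 1), (1, 0, 3), (3, 1, 5), (5, 3, 7), (13, 11, 15),
         (15, 13, 17)],
    )
    def test_default_lattice_brackets(self, value, lo, hi):
        spec = GridSpec()
        r = random_range(value, spec)
        assert (r.lo, r.hi) == (lo, hi)
        assert r.lo <= value < r.hi

    def test_off_lattice_value_rejected(self):
        with pytest.raises(ValueError):
            random_range(2, GridSpec())
        with pytest.raises(ValueError):
            RandomRange(lo=3, hi=3)


def _brute_force_grid(matrix, y, spec):
    """Independent oracle: full double loop with explicit tie-breaking."""
    best = None
    for w in sorted(itertools.product(spec.allowed_weights,
                                      repeat=spec.n_predictors)):
        if sum(w) != spec.weight_sum:
            continue
        scores = matrix.calls.astype(float) @ np.asarray(w, dtype=float)
        for t in spec.t_candidates:
            rep = evaluate_binary((scores >= t).astype(int), y)
            key = (rep.mcc, rep.acc)
            if best is None or key > best[0]:
                best = (key, w, t)
    return best


class TestRestrictedGridSearch:
    def test_matches_brute_force_small(self, small_ensemble):
        matrix, y = small_ensemble
        spec = GridSpec(allowed_weights=(0, 1, 3), weight_sum=3,
                        n_predictors=3, t_candidates=(0, 1, 2, 3))
        res = restricted_grid_search(matrix, y, spec)
        (key, w, t) = _brute_force_grid(matrix, y, spec)
        assert tuple(res.best.weights) == w
        assert res.best.threshold == t
        assert res.best_mcc == pytest.approx(key[0])
        assert res.n_evaluated == sum(
            1 for _ in enumerate_compositions(spec)) * 4

    def test_single_predictor_grid(self):
        y = np.array([1, 0, 1, 0, 1, 0])
        m = matrix_of(np.c_[np.array([1, 0, 1, 0, 1, 1])])
        spec = GridSpec(allowed_weights=(0, 1), weight_sum=1, n_predictors=1,
                        t_candidates=(0, 1))
        res = restricted_grid_search(m, y, spec)
        best = _brute_force_grid(m, y, spec)
        assert (tuple(res.best.weights), res.best.threshold) == best[1:]
        assert res.best.threshold <= 1

    def test_perfect_predictor_gets_all_weight(self):
        """With one perfect predictor among coin-flips, it takes the max weight."""
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=200)
        calls = np.c_[y, rng.integers(0, 2, 200), rng.integers(0, 2, 200)]
        spec = GridSpec(allowed_weights=(0, 1, 3), weight_sum=3,
                        n_predictors=3)
        res = restricted_grid_search(matrix_of(calls), y, spec)
        assert res.best.weights[0] == 3
        assert res.best_mcc == pytest.approx(1.0)

    def test_self_consistency_of_reported_objective(self, small_ensemble):
        matrix, y = small_ensemble
        spec = GridSpec(allowed_weights=(0, 1, 3), weight_sum=3,
                        n_predictors=3)
        res = restricted_grid_search(matrix, y, spec)
        rep = evaluate_binary(res.best.predict(matrix), y)
        assert rep.mcc == pytest.approx(res.best_mcc)
        assert rep.acc == pytest.approx(res.best_acc)

    def test_infeasible_grid_raises(self, small_ensemble):
        matrix, y = small_ensemble
        spec = GridSpec(allowed_weights=(0, 4), weight_sum=3, n_predictors=3)
        with pytest.raises(ValueError, match="infeasible"):
            restricted_grid_search(matrix, y, spec)


@pytest.fixture(scope="module")
def seeded():
    spec = EnsembleSpec(n_sites=300, positive_fraction=0.5,
                        sn=(0.9, 0.75, 0.6), sp=(0.85, 0.7, 0.65),
                        rho=0.2, seed=11)
    matrix, y = simulate_ensemble(spec)
    gspec = GridSpec(allowed_weights=(0, 1, 3), weight_sum=3,
                     n_predictors=3)
    grid = restricted_grid_search(matrix, y, gspec)
    return matrix, y, gspec, grid


class TestConditionalRandomSearch:

    def test_never_below_grid_result(self, seeded):
        matrix, y, gspec, grid = seeded
        for seed in range(30):
            res = conditional_random_search(matrix, y, grid, gspec,
                                            rng_seed=seed, max_iter=50)
            assert res.best_mcc >= grid.best_mcc

    def test_deterministic_from_seed(self, seeded):
        matrix, y, gspec, grid = seeded
        a = conditional_random_search(matrix, y, grid, gspec, rng_seed=5,
                                      max_iter=100)
        b = conditional_random_search(matrix, y, grid, gspec, rng_seed=5,
                                      max_iter=100)
        assert np.array_equal(a.best.weights, b.best.weights)
        assert a.best.threshold == b.best.threshold
        assert a.n_evaluated == b.n_evaluated
        assert a.trace == b.trace

    def test_cannot_exceed_perfect_grid_solution(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=100)
        calls = np.c_[y, rng.integers(0, 2, 100)]
        gspec = GridSpec(allowed_weights=(0, 1), weight_sum=1, n_predictors=2)
        grid = restricted_grid_search(matrix_of(calls), y, gspec)
        assert grid.best_mcc == pytest.approx(1.0)
        res = conditional_random_search(matrix_of(calls), y, grid, gspec,
                                        rng_seed=0, max_iter=20)
        assert res.converged is False
        assert res.n_evaluated == 20
        assert np.array_equal(res.best.weights, grid.best.weights)

    def test_refined_weights_stay_in_brackets(self, seeded):
        matrix, y, gspec, grid = seeded
        res = conditional_random_search(matrix, y, grid, gspec, rng_seed=3,
                                        max_iter=200)
        if res.converged:
            for w_ref, w_grid in zip(res.best.weights, grid.best.weights):
                r = random_range(int(w_grid), gspec)
                assert r.lo <= w_ref < r.hi
            assert 0 <= res.best.threshold < res.best.weights.sum()

    def test_max_iter_validated(self, seeded):
        matrix, y, gspec, grid = seeded
        with pytest.raises(ValueError):
            conditional_random_search(matrix, y, grid, gspec, rng_seed=0,
                                      max_iter=0)
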