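"""B(k)/W(k) feature explanations: objective identities and solver quality."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cskl
from cskl.exceptions import ParameterError, ValidationError
from cskl.explanation import explain_pair, explain_set, restricted_objective

from .conftest import random_representation


def selector(n, indices):
    S = np.zeros(n, dtype=int)
    S[list(indices)] = 1
    return S


def brute_force(repP, repQ, k, mode="best"):
    pick = min if mode == "best" else max
    return pick(
        restricted_objective(repP, repQ, selector(repP.n, idx))
        for idx in itertools.combinations(range(repP.n), k)
    )


@pytest.fixture()
def rep_pair():
    rng = np.random.default_rng(0)
    return (
        random_representation(40, 4, 0.5, rng, "P"),
        random_representation(40, 3, 0.5, rng, "Q"),
    )


class TestRestrictedObjective:
    def test_all_ones_equals_unrestricted_divergence(self, rep_pair):
        repP, repQ = rep_pair
        full = restricted_objective(repP, repQ, np.ones(40, dtype=int))
        assert full == pytest.approx(cskl.cskl(repP, repQ), abs=1e-8)

    def test_all_zeros_is_the_maximum(self, rep_pair):
        repP, repQ = rep_pair
        value = restricted_objective(repP, repQ, np.zeros(40, dtype=int))
        assert value == pytest.approx(0.5 * 40 / 0.5)  # alpha*n/(1-alpha)

    def test_identical_representations_monotone_under_supersets(self):
        rng = np.random.default_rng(1)
        rep = random_representation(30, 3, 0.5, rng)
        order = rng.permutation(30)
        values = [
            restricted_objective(rep, rep, selector(30, order[:size]))
            for size in (5, 10, 20, 30)
        ]
        assert all(v >= 0 for v in values)
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_wrong_length_rejected(self, rep_pair):
        with pytest.raises(ValidationError):
            restricted_objective(*rep_pair, np.ones(17, dtype=int))


class TestExplainPair:
    def test_k_equals_n_selects_everything(self, rep_pair):
        repP, repQ = rep_pair
        result = explain_pair(repP, repQ, k=40)
        assert result.selected == tuple(range(40))
        assert result.objective == pytest.approx(cskl.cskl(repP, repQ), abs=1e-8)
        assert result.converged and result.iterations <= 2

    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(2)
        matches = 0
        for inst in range(10):
            repP = random_representation(10, 2, 0.5, rng, "P")
            repQ = random_representation(10, 2, 0.5, rng, "Q")
            optimum = brute_force(repP, repQ, 3)
            result = explain_pair(repP, repQ, 3, seed=inst, n_restarts=10)
            assert result.objective >= optimum - 1e-9  # brute force is truly optimal
            matches += abs(result.objective - optimum) < 1e-9
        assert matches >= 8

    def test_recovers_planted_shared_variables(self):
        spec = cskl.random_covariance_spec(100, 3, signal_fraction=0.1, seed=5)
        reps = [
            cskl.decompose(
                cskl.standardize(cskl.sample_dataset(spec, 80, f"d{i}", seed=i + 1)), 0.5
            )
            for i in range(2)
        ]
        result = explain_pair(reps[0], reps[1], k=10, seed=0)
        hits = len(set(result.selected) & set(spec.active_variables))
        assert hits >= 8

    def test_monotone_trace_and_best_below_worst(self, rep_pair):
        repP, repQ = rep_pair
        for k in (5, 15):
            best = explain_pair(repP, repQ, k, mode="best", seed=3)
            worst = explain_pair(repP, repQ, k, mode="worst", seed=3)
            assert all(
                b >= a - 1e-9 for a, b in zip(best.trace, best.trace[1:])
            )  # bilinear ascent
            assert all(b <= a + 1e-9 for a, b in zip(worst.trace, worst.trace[1:]))
            assert best.objective <= worst.objective + 1e-9

    def test_beats_random_selectors(self, rep_pair):
        repP, repQ = rep_pair
        rng = np.random.default_rng(6)
        result = explain_pair(repP, repQ, 8, seed=4)
        randoms = [
            restricted_objective(repP, repQ, selector(40, rng.choice(40, 8, replace=False)))
            for _ in range(100)
        ]
        assert result.objective <= min(randoms) + 1e-9

    def test_invalid_k_rejected(self, rep_pair):
        with pytest.raises(ParameterError):
            explain_pair(*rep_pair, k=41)
        with pytest.raises(ParameterError):
            explain_pair(*rep_pair, k=0)


class TestExplainSet:
    def test_single_pair_matches_explain_pair(self, rep_pair):
        single = explain_set([rep_pair], k=7, seed=9)
        direct = explain_pair(*rep_pair, k=7, seed=9)
        assert single.selected == direct.selected
        assert single.objective == pytest.approx(direct.objective)

    def test_duplicated_pairs_double_objective_same_selection(self, rep_pair):
        once = explain_set([rep_pair], k=7, seed=9)
        twice = explain_set([rep_pair, rep_pair], k=7, seed=9)
        assert twice.selected == once.selected
        assert twice.objective == pytest.approx(2 * once.objective)

    def test_shared_mechanism_dominates_selection(self, crosslink_collection):
        datasets, _, truth = crosslink_collection
        reps = {d.dataset_id: cskl.decompose(cskl.standardize(d), 0.5) for d in datasets}
        cross = truth[truth["relation"] == "cross_link"]
        pairs = [(reps[r.id_a], reps[r.id_b]) for r in cross.itertuples()]
        result = explain_set(pairs[:3], k=20, seed=0)
        assert len(set(result.selected) & set(range(20))) >= 10

    def test_empty_pair_list_rejected(self):
        with pytest.raises(ValidationError):
            explain_set([], k=3)


class TestExplanationCurve:
    def test_full_k_coincides_with_divergence(self, rep_pair):
        repP, repQ = rep_pair
        curve = cskl.explanation_curve(repP, repQ, [40], n_random=5, seed=0)
        assert curve.loc[0, "objective_best"] == pytest.approx(
            cskl.cskl(repP, repQ), abs=1e-8
        )
        assert curve.loc[0, "random_mean"] == pytest.approx(
            cskl.cskl(repP, repQ), abs=1e-8
        )

    def test_optimized_below_random_on_similar_pair(self, small_reps):
        repP, repQ = small_reps[0], small_reps[1]  # same disease group
        curve = cskl.explanation_curve(repP, repQ, [10, 30, 60], n_random=50, seed=1)
        assert (curve["objective_best"] < curve["random_mean"]).all()


class TestJaccard:
    def test_known_values(self):
        assert cskl.jaccard({"a", "b", "c"}, {"a", "b", "c"}) == 1.0
        assert cskl.jaccard({"a"}, {"b"}) == 0.0
        assert cskl.jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError):
            cskl.jaccard(set(), set())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.sets(st.integers(0, 30), max_size=10),
        st.sets(st.integers(0, 30), max_size=10),
    )
    def test_bounds_and_symmetry(self, A, B):
        if not A and not B:
            return
        j = cskl.jaccard(A, B)
        assert 0.0 <= j <= 1.0
        assert j == cskl.jaccard(B, A)
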