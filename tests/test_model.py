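"""Core types: validation, projection/consistency arithmetic, greedy solution, feasibility."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paction import (
    CloneTree,
    ValidationError,
    check_refinement,
    consistency_error,
    consistent_proportions_for_clone_set,
    greedy_trivial_solution,
    project_proportions,
    support,
    validate_proportion_matrix,
)
from conftest import random_proportions


class TestValidateProportionMatrix:
    @pytest.mark.parametrize(
        "raw",
        [[[1.0]], [[0.5, 0.5], [0.2, 0.8]], [[0.3, 0.3, 0.4]]],
    )
    def test_valid_matrices_accepted(self, raw):
        U = validate_proportion_matrix(raw)
        assert U.values.shape == (len(raw), len(raw[0]))
        np.testing.assert_allclose(U.values.sum(axis=1), 1.0)

    def test_row_sum_violation_names_the_sample(self):
        with pytest.raises(ValidationError, match="sample 1"):
            validate_proportion_matrix([[0.5, 0.6]], tolerance=1e-6)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            validate_proportion_matrix([[1.2, -0.2]])

    def test_renormalization_within_tolerance(self):
        U = validate_proportion_matrix([[0.5, 0.5 + 5e-7]], tolerance=1e-6, renormalize=True)
        np.testing.assert_allclose(U.values.sum(axis=1), 1.0, atol=1e-15)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            validate_proportion_matrix([[0.5, 0.5]], clone_ids=["a", "a"])


class TestProjection:
    def test_single_pair_projects_to_itself(self):
        U = validate_proportion_matrix([[1.0]], clone_ids=[(1, 1)])
        assert project_proportions({(1, 1)}, U, 1).values.tolist() == [[1.0]]

    @pytest.mark.parametrize(
        "feature,expected",
        [(1, [[0.5, 0.5], [1.0, 0.0]]), (2, [[0.2, 0.8], [1.0, 0.0]])],
    )
    def test_marginalization_sums_projection_classes(self, feature, expected):
        clones = [(1, 1), (1, 2), (2, 2)]
        U = validate_proportion_matrix([[0.2, 0.3, 0.5], [1.0, 0.0, 0.0]], clone_ids=clones)
        proj = project_proportions(clones, U, feature, target_clone_ids=(1, 2))
        np.testing.assert_allclose(proj.values, expected)

    def test_absent_target_clone_gets_zero_column(self):
        clones = [(1, 1)]
        U = validate_proportion_matrix([[1.0]], clone_ids=clones)
        proj = project_proportions(clones, U, 2, target_clone_ids=(1, 2))
        np.testing.assert_allclose(proj.values, [[1.0, 0.0]])


class TestConsistencyError:
    def test_consistent_by_construction(self):
        clones = [(1, 1), (1, 2), (2, 2)]
        U = validate_proportion_matrix([[0.2, 0.3, 0.5]], clone_ids=clones)
        U1 = validate_proportion_matrix([[0.5, 0.5]])
        U2 = validate_proportion_matrix([[0.2, 0.8]])
        assert consistency_error(clones, U, U1, U2) == pytest.approx(0.0, abs=1e-12)

    def test_l1_deviation_of_both_marginals(self):
        clones = [(1, 1), (2, 2)]
        U = validate_proportion_matrix([[0.5, 0.5]], clone_ids=clones)
        U1 = validate_proportion_matrix([[0.5, 0.5]])
        U2 = validate_proportion_matrix([[0.6, 0.4]])
        assert consistency_error(clones, U, U1, U2) == pytest.approx(0.2)

    def test_missing_column_counts_fully(self):
        clones = [(1, 1)]
        U = validate_proportion_matrix([[1.0]], clone_ids=clones)
        U1 = validate_proportion_matrix([[1.0]])
        U2 = validate_proportion_matrix([[0.5, 0.5]])
        assert consistency_error(clones, U, U1, U2) == pytest.approx(1.0)

    def test_projection_of_own_marginals_is_exactly_consistent(self, rng):
        # invariant: U is always consistent with its own projections
        for _ in range(20):
            n1, n2 = rng.integers(1, 5, size=2)
            pairs = [
                (i, j)
                for i in range(1, n1 + 1)
                for j in range(1, n2 + 1)
                if rng.random() < 0.7
            ] or [(1, 1)]
            U = random_proportions(int(rng.integers(1, 4)), len(pairs), rng, labels=pairs)
            U1 = project_proportions(pairs, U, 1)
            U2 = project_proportions(pairs, U, 2)
            assert consistency_error(pairs, U, U1, U2) == 0.0


class TestSupport:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([[1.0]], 1),
            ([[0.5, 0.5, 0.0]], 2),
            ([[0.5, 0.0, 0.5], [0.0, 1.0, 0.0]], 3),
        ],
    )
    def test_counts_clones_with_nonzero_total(self, raw, expected):
        assert support(validate_proportion_matrix(raw)) == expected


class TestCloneTree:
    def test_root_inference_and_vertices(self):
        T = CloneTree.from_edges([(1, 2), (1, 3), (3, 4)])
        assert T.root == 1
        assert T.vertices == {1, 2, 3, 4}
        assert T.parent(4) == 3 and T.parent(1) is None

    def test_cycle_rejected(self):
        with pytest.raises(ValidationError):
            CloneTree.from_edges([(1, 2), (2, 1)])

    def test_two_parents_rejected(self):
        with pytest.raises(ValidationError, match="more than one parent"):
            CloneTree.from_edges([(1, 3), (2, 3), (1, 2)])

    def test_disconnected_rejected(self):
        with pytest.raises(ValidationError):
            CloneTree.from_edges([(1, 2), (3, 4)], root=1)


class TestCheckRefinement:
    def test_single_vertices_pass(self):
        T = CloneTree.single_vertex((1, 1))
        assert check_refinement(T, CloneTree.single_vertex(1), CloneTree.single_vertex(1)).ok

    def test_chain_realizing_each_edge_once_passes(self):
        T1 = CloneTree.from_edges([(1, 2)])
        T2 = CloneTree.from_edges([(1, 2)])
        T = CloneTree.from_edges([((1, 1), (1, 2)), ((1, 2), (2, 2))])
        assert check_refinement(T, T1, T2).ok

    def test_double_coordinate_change_fails_condition_iii(self):
        T1 = CloneTree.from_edges([(1, 2)])
        T2 = CloneTree.from_edges([(1, 2)])
        T = CloneTree.from_edges([((1, 1), (2, 2))])
        result = check_refinement(T, T1, T2)
        assert not result.ok
        assert any("condition (iii)" in v for v in result.violations)
        # the unrealized input edges are also reported
        assert any("condition (i)" in v for v in result.violations)

    def test_wrong_root_fails(self):
        T1 = CloneTree.from_edges([(1, 2)])
        T2 = CloneTree.single_vertex(1)
        T = CloneTree.from_edges([((2, 1), (1, 1))], root=(2, 1))
        result = check_refinement(T, T1, T2)
        assert not result.ok and any("root" in v for v in result.violations)


class TestGreedyTrivialSolution:
    def test_single_clone(self):
        sol = greedy_trivial_solution(
            validate_proportion_matrix([[1.0]]), validate_proportion_matrix([[1.0]])
        )
        assert sol.clones == {(1, 1)}
        np.testing.assert_allclose(sol.proportions.values, [[1.0]])

    def test_row_major_hand_execution(self):
        sol = greedy_trivial_solution(
            validate_proportion_matrix([[0.5, 0.5]]), validate_proportion_matrix([[0.3, 0.7]])
        )
        got = dict(zip(sol.proportions.clone_ids, sol.proportions.values[0]))
        assert got == pytest.approx({(1, 1): 0.3, (1, 2): 0.2, (2, 1): 0.0, (2, 2): 0.5})

    def test_order_dependence_hand_execution(self):
        order = [(1, 2), (2, 1), (1, 1), (2, 2)]
        sol = greedy_trivial_solution(
            validate_proportion_matrix([[0.5, 0.5]]),
            validate_proportion_matrix([[0.5, 0.5]]),
            order=order,
        )
        got = dict(zip(sol.proportions.clone_ids, sol.proportions.values[0]))
        assert got == pytest.approx({(1, 2): 0.5, (2, 1): 0.5, (1, 1): 0.0, (2, 2): 0.0})

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        weights1=st.lists(st.integers(1, 50), min_size=1, max_size=4),
        weights2=st.lists(st.integers(1, 50), min_size=1, max_size=4),
        m=st.integers(1, 3),
        order_seed=st.integers(0, 2**31 - 1),
    )
    def test_always_consistent_for_any_order(self, weights1, weights2, m, order_seed):
        """The greedy construction is consistent for random inputs and visit orders."""
        rng = np.random.default_rng(order_seed)
        U1 = random_proportions(m, len(weights1), rng)
        U2 = random_proportions(m, len(weights2), rng)
        pairs = list(itertools.product(U1.clone_ids, U2.clone_ids))
        order = [pairs[k] for k in rng.permutation(len(pairs))]
        sol = greedy_trivial_solution(U1, U2, order=order)
        assert consistency_error(sol.clones, sol.proportions, U1, U2) == pytest.approx(0.0, abs=1e-9)


class TestConsistentProportionsForCloneSet:
    def test_full_pair_set_always_feasible(self, rng):
        for _ in range(30):
            n1, n2, m = (int(v) for v in rng.integers(1, 5, size=3))
            U1 = random_proportions(min(m, 3), n1, rng)
            U2 = random_proportions(min(m, 3), n2, rng)
            pairs = list(itertools.product(U1.clone_ids, U2.clone_ids))
            U = consistent_proportions_for_clone_set(pairs, U1, U2)
            assert U is not None
            assert consistency_error(pairs, U, U1, U2) == pytest.approx(0.0, abs=1e-6)

    def test_infeasible_diagonal(self):
        U1 = validate_proportion_matrix([[0.5, 0.5]])
        U2 = validate_proportion_matrix([[0.6, 0.4]])
        assert consistent_proportions_for_clone_set([(1, 1), (2, 2)], U1, U2) is None

    def test_unique_three_clone_solution(self):
        U1 = validate_proportion_matrix([[0.5, 0.5]])
        U2 = validate_proportion_matrix([[0.6, 0.4]])
        U = consistent_proportions_for_clone_set([(1, 1), (2, 1), (2, 2)], U1, U2)
        got = dict(zip(U.clone_ids, U.values[0]))
        assert got == pytest.approx({(1, 1): 0.5, (2, 1): 0.1, (2, 2): 0.4}, abs=1e-9)

    def test_flow_and_lp_agree_on_single_sample_feasibility(self, rng):
        """For m=1 the max-flow construction and the LP report the same feasibility."""
        for _ in range(40):
            n1, n2 = (int(v) for v in rng.integers(1, 5, size=2))
            U1 = random_proportions(1, n1, rng)
            U2 = random_proportions(1, n2, rng)
            pairs = [
                p
                for p in itertools.product(U1.clone_ids, U2.clone_ids)
                if rng.random() < 0.6
            ]
            if not pairs:
                continue
            flow = consistent_proportions_for_clone_set(pairs, U1, U2, method="flow")
            lp = consistent_proportions_for_clone_set(pairs, U1, U2, method="lp")
            assert (flow is None) == (lp is None)

    def test_flow_method_rejects_multiple_samples(self, rng):
        U1 = random_proportions(2, 2, rng)
        U2 = random_proportions(2, 2, rng)
        with pytest.raises(ValueError, match="single sample"):
            consistent_proportions_for_clone_set([((1), (1))], U1, U2, method="flow")
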