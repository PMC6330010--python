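"""Consistency, flux variability, nullspace and dependency detection."""

import numpy as np
import pytest

import fluxtopes as ft
from fluxtopes.preprocess import _as_fraction_matrix


class TestFluxVariability:
    def test_polyhedron_bounds_match_published_values(self, toy_bounded):
        fva = ft.flux_variability(toy_bounded)
        assert fva[1][1] == pytest.approx(30.0)   # max v2
        assert fva[2][0] == pytest.approx(-5.0)   # min v3
        assert fva[3][1] == pytest.approx(10.0)   # max v4
        assert fva[4][0] == pytest.approx(-10.0)  # min v5
        assert np.isneginf(fva[3][0])             # v4 unbounded below
        assert np.isposinf(fva[4][1])             # v5 unbounded above

    def test_unbounded_cone_reports_infinity(self, toy):
        fva = ft.flux_variability(toy)
        assert np.isposinf(fva[0][1])

    def test_bounds_bracket_enumeration_witnesses(self, toy, toy_topes):
        fva = ft.flux_variability(toy)
        for tope in toy_topes.topes:
            for i, v in enumerate(tope.witness):
                assert fva[i][0] - 1e-7 <= v <= fva[i][1] + 1e-7

    def test_infeasible_system_raises(self, toy):
        from fluxtopes._lp import InfeasibleError
        c = np.eye(6)[0]
        with pytest.raises(InfeasibleError):
            ft.flux_variability(toy, extra=(c, -5.0))  # v1 = -5 impossible


class TestMakeConsistent:
    def test_toy_already_consistent(self, toy):
        net, report = ft.make_consistent(toy)
        assert report.unchanged
        np.testing.assert_array_equal(net.N, toy.N)

    def test_dead_end_reaction_removed(self, toy):
        # add internal metabolite D produced by a new reaction, never consumed
        N = np.zeros((4, 7))
        N[:3, :6] = toy.N
        N[0, 6] = -1.0
        N[3, 6] = 1.0
        net = ft.MetabolicNetwork(
            N=N, metabolite_ids=("A", "B", "C", "D"),
            reaction_ids=toy.reaction_ids + ("R7",),
            reversible=np.append(toy.reversible, False))
        fixed, report = ft.make_consistent(net)
        assert report.removed == ["R7"]
        assert fixed.r == 6

    def test_idempotent(self):
        net = ft.random_network(4, 8, 4, seed=3)
        once, r1 = ft.make_consistent(net)
        twice, r2 = ft.make_consistent(once)
        assert r2.unchanged
        np.testing.assert_array_equal(once.N, twice.N)

    def test_backward_only_reversible_flipped(self):
        # A -> via R1; R2 written as A -> (consumes A) but reversible:
        # steady state forces R2 backwards, so its column is negated.
        net = ft.MetabolicNetwork(
            N=np.array([[1.0, 1.0]]), metabolite_ids=("A",),
            reaction_ids=("R1", "R2"),
            reversible=np.array([False, True]))
        fixed, report = ft.make_consistent(net)
        assert report.fixed_backward == ["R2"]
        np.testing.assert_array_equal(fixed.N, [[1.0, -1.0]])
        assert not fixed.reversible[1]

    def test_all_blocked_raises(self):
        net = ft.MetabolicNetwork(
            N=np.array([[1.0, 1.0]]), metabolite_ids=("A",),
            reaction_ids=("R1", "R2"),
            reversible=np.array([False, False]))
        with pytest.raises(ft.EmptyModelError):
            ft.make_consistent(net)


class TestNullspace:
    def test_toy_dimension_and_annihilation(self, toy):
        K = ft.nullspace_basis(toy.N)
        assert K.shape == (6, 3)
        np.testing.assert_allclose(toy.N @ K, 0, atol=1e-12)
        assert np.linalg.matrix_rank(K) == 3

    def test_free_coordinate_basis_reproduces_published_matrix(self, toy):
        K = ft.nullspace_basis(toy.N, free=[0, 1, 3])
        expected = np.array([[1, 0, 0], [0, 1, 0], [-0.5, 0.5, 0],
                             [0, 0, 1], [0, 1, -1], [1, 0, -1]], float)
        np.testing.assert_allclose(K, expected, atol=1e-12)
        np.testing.assert_allclose(K[[0, 1, 3]], np.eye(3), atol=1e-12)

    def test_trivial_nullspace_raises(self):
        with pytest.raises(ft.NoFluxError):
            ft.nullspace_basis(np.eye(3))

    def test_irrational_matrix_falls_back_to_svd(self):
        N = np.array([[np.sqrt(2.0), -1.0, 0.0]])
        K = ft.nullspace_basis(N)
        assert _as_fraction_matrix(N) is None
        np.testing.assert_allclose(N @ K, 0, atol=1e-9)
        assert K.shape == (3, 2)


class TestReactionDependencies:
    def test_toy_all_independent(self, toy):
        deps = ft.reaction_dependencies(ft.nullspace_basis(toy.N))
        assert deps.r_ind == 6
        assert deps.dependent == {}

    def test_chain_rows_coupled_with_positive_sign(self, chain):
        deps = ft.reaction_dependencies(ft.nullspace_basis(chain.N))
        assert deps.r_ind == 1
        assert deps.dependent == {1: (0, 1)}

    def test_negative_multiple_detected(self):
        K = np.array([[1.0, 2.0], [0.0, 1.0], [-2.0, -4.0]])
        deps = ft.reaction_dependencies(K)
        assert deps.dependent[2] == (0, -1)
        assert deps.members(0) == [0, 2]

    def test_zero_row_is_an_error(self):
        with pytest.raises(ft.InconsistencyError):
            ft.reaction_dependencies(np.array([[1.0], [0.0]]))

    def test_flipping_dependent_alone_is_infeasible(self, chain):
        # fluxes through an unbranched chain are equal; opposite signs
        # cannot be realized
        tau = ft.FullSignVector("+-", chain.irr_mask)
        ok, _ = ft.check_tope_feasible(chain, tau)
        assert not ok
        ok, _ = ft.check_tope_feasible(
            chain, ft.FullSignVector("--", chain.irr_mask))
        assert ok


class TestInitialTope:
    def test_toy_all_plus_no_flips(self, toy):
        tau, flips = ft.initial_tope(toy)
        assert str(tau) == "++++++"
        assert flips == []
        ok, witness = ft.check_tope_feasible(toy, tau)
        assert ok and (witness > 0).all()

    def test_initial_tope_always_feasible_on_random_networks(self):
        for seed in (0, 1, 2):
            net = ft.random_network(4, 8, 4, seed=seed)
            tau, flips = ft.initial_tope(net)
            oriented = net.with_flipped_columns(flips) if flips else net
            ok, _ = ft.check_tope_feasible(oriented, tau)
            assert ok

    def test_inconsistent_network_raises(self):
        net = ft.MetabolicNetwork(
            N=np.array([[1.0, 1.0]]), metabolite_ids=("A",),
            reaction_ids=("R1", "R2"),
            reversible=np.array([False, False]))
        with pytest.raises(ft.InconsistencyError):
            ft.initial_tope(net)


def test_full_support_after_consistency_on_random_networks():
    """On a consistent cone, every enumerated tope has full support and a
    full-support witness."""
    for seed in (0, 5):
        net = ft.random_network(4, 8, 4, seed=seed)
        res = ft.enumerate_topes(net, assume_consistent=True)
        for tope in res.topes:
            assert tope.tau.has_full_support()
            assert (np.abs(tope.witness) > 1e-7).all()
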