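"""Per-tope EFM enumeration, deduplication, and the tope/EFM duality."""

import numpy as np
import pytest

import fluxtopes as ft
from fluxtopes.efm import support_minimal

INTERNAL_CYCLE = (0, 0, 0, -1, 1, 1)  # primitive form of the A-B-C loop


class TestEfmsInTope:
    def test_three_efms_per_toy_tope(self, toy, toy_topes):
        for tope in toy_topes.topes:
            efm_set = ft.enumerate_efms_in_tope(toy, tope.tau)
            assert len(efm_set) == 3

    def test_members_conform_to_tope(self, toy, toy_topes):
        for tope in toy_topes.topes:
            for e in ft.enumerate_efms_in_tope(toy, tope.tau):
                assert e.conforms_to(tope.tau)

    def test_infeasible_sign_vector_rejected(self, toy):
        tau = ft.FullSignVector("++++-+", toy.irr_mask)
        with pytest.raises(ValueError):
            ft.enumerate_efms_in_tope(toy, tau)

    def test_internal_cycle_in_exactly_its_conforming_topes(self, toy,
                                                            toy_topes):
        cycle = ft.EFM(flux=INTERNAL_CYCLE)
        containing = {str(t.tau) for t in toy_topes.topes
                      if cycle.conforms_to(t.tau)}
        assert len(containing) == 2
        for tope in toy_topes.topes:
            efms = ft.enumerate_efms_in_tope(toy, tope.tau)
            assert (INTERNAL_CYCLE in efms.keys()) == (
                str(tope.tau) in containing)

    def test_steady_state_and_support_minimality(self, toy, toy_efms):
        efm_set, _ = toy_efms
        for e in efm_set:
            np.testing.assert_allclose(toy.N @ e.as_array(), 0, atol=1e-12)
            assert support_minimal(toy, e)

    def test_deleting_a_support_reaction_kills_the_mode(self, toy,
                                                        toy_efms):
        """Extreme-ray criterion: on the support, the steady-state system
        has a one-dimensional solution space; removing any support member
        leaves only zero."""
        efm_set, _ = toy_efms
        for e in efm_set:
            sup = sorted(e.support)
            for drop in sup:
                rest = [i for i in sup if i != drop]
                Ns = toy.N[:, rest]
                null_dim = len(rest) - np.linalg.matrix_rank(Ns)
                assert null_dim == 0


class TestGlobalEfms:
    def test_six_distinct_efms(self, toy_efms):
        efm_set, summary = toy_efms
        assert len(efm_set) == 6
        assert summary["n_topes"] == 5

    def test_duplication_factor_fifteen_sixths(self, toy_efms):
        _, summary = toy_efms
        assert summary["duplication_factor"] == pytest.approx(15 / 6)

    def test_most_contained_efm_in_four_topes(self, toy_topes, toy_efms):
        efm_set, _ = toy_efms
        counts = {e.flux: sum(1 for t in toy_topes.topes
                              if e.conforms_to(t.tau))
                  for e in efm_set}
        assert max(counts.values()) == 4
        assert sorted(counts.values(), reverse=True) == [4, 3, 3, 2, 2, 1]
        assert counts[(1, 1, 0, 0, 1, 1)] == 4

    def test_single_tope_network_equals_global(self):
        net = ft.random_network(3, 6, 0, seed=2)
        result = ft.enumerate_topes(net, assume_consistent=True)
        assert len(result) == 1
        per_tope = ft.enumerate_efms_in_tope(net, result.topes[0].tau)
        global_set, _ = ft.enumerate_efms_via_topes(net, result=result)
        assert per_tope.keys() == global_set.keys()

    def test_orientation_invariance(self, toy):
        """Flipping a reversible column yields the same EFMs up to the
        sign of that component."""
        flipped = toy.with_flipped_columns([3])
        a, _ = ft.enumerate_efms_via_topes(toy)
        b, _ = ft.enumerate_efms_via_topes(flipped)
        def unflip(flux):
            f = list(flux)
            f[3] = -f[3]
            return tuple(f)
        assert a.keys() == {unflip(f) for f in b.keys()}


class TestConformalDecomposition:
    def test_sum_of_two_efms_decomposes(self, toy, toy_efms):
        efm_set, _ = toy_efms
        efms = sorted(efm_set, key=lambda e: e.flux)
        v = efms[2].as_array() + efms[3].as_array()  # e4-like + e1-like
        ok, lam = ft.conformal_decomposition_check(v, efm_set)
        assert ok and (lam >= -1e-12).all()

    def test_every_tope_witness_decomposes_within_its_tope(self, toy,
                                                           toy_topes):
        for tope in toy_topes.topes:
            efms = ft.enumerate_efms_in_tope(toy, tope.tau)
            ok, lam = ft.conformal_decomposition_check(tope.witness, efms)
            assert ok
            recon = sum(l * e.as_array() for l, e in zip(lam, efms))
            np.testing.assert_allclose(recon, tope.witness, atol=1e-6)

    def test_zero_vector_trivially_decomposes(self, toy_efms):
        efm_set, _ = toy_efms
        ok, lam = ft.conformal_decomposition_check(np.zeros(6), efm_set)
        assert ok

    def test_vector_outside_cone_fails(self, toy, toy_efms):
        efm_set, _ = toy_efms
        ok, _ = ft.conformal_decomposition_check(
            np.array([-1.0, 0, 0, 0, 0, 0]), efm_set)  # R1 irreversible
        assert not ok


class TestTopeEfmDuality:
    def test_toy_duality_holds(self, toy):
        report = ft.verify_tope_efm_duality(toy)
        assert report["ok"]
        assert report["union_equals_global"]
        assert not report["violations"]["conforming_mismatch"]
        assert not report["violations"]["not_maximal"]

    @pytest.mark.parametrize("seed", [0, 3, 6])
    def test_duality_on_random_networks(self, seed):
        net = ft.random_network(m=3, r=7, n_rev=3, seed=seed)
        report = ft.verify_tope_efm_duality(net)
        assert report["ok"], report["violations"]
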