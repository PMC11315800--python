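"""Vertex condensation, the fragment bank, and integral budgets."""

import numpy as np
import pytest

from chemion.bank import FragmentBank, fragment_key, geometry_hash
from chemion.condense import (CondensationError, condense_fock,
                              condense_fock_block, condense_integrals,
                              condense_normalization, integral_budget,
                              one_chemion_matrix)
from chemion.molecule import (bond_split, build_chain, chain_bond_ensemble,
                              full_molecule_ensemble, set_torsion)
from chemion.rhf import build_fock, density_matrix, scf, solve_roothaan
from chemion.sto import build_anchor_integrals, vertex_orbitals


class TestNormalization:
    def test_singleton_identity(self):
        assert condense_normalization([0], np.eye(3)) == pytest.approx(1.0)

    def test_two_orthonormal_members(self):
        assert condense_normalization([0, 1], np.eye(2)) == pytest.approx(1 / np.sqrt(2))

    def test_two_overlapping_members(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert condense_normalization([0, 1], S) == pytest.approx(1 / np.sqrt(3))

    def test_pathological_overlap_rejected(self):
        S = np.array([[1.0, -1.5], [-1.5, 1.0]])
        with pytest.raises(CondensationError):
            condense_normalization([0, 1], S)


class TestCondensedIntegrals:
    def test_singleton_groups_reproduce_raw_integrals(self, methane_integrals):
        cond, orbs = condense_integrals(methane_integrals, [[i] for i in range(5)])
        assert np.abs(cond.S - methane_integrals.S).max() < 1e-14
        assert np.abs(cond.K - methane_integrals.K).max() < 1e-14
        assert np.abs(cond.U - methane_integrals.U).max() < 1e-14
        assert np.abs(cond.R - methane_integrals.R).max() < 1e-14
        assert all(o.norm == pytest.approx(1.0) for o in orbs)

    def test_condensed_unit_diagonal(self, ethane, ethane_integrals):
        groups = list(bond_split(ethane, 0))
        cond, _ = condense_integrals(ethane_integrals, groups)
        assert cond.S.shape == (2, 2)
        assert np.abs(np.diag(cond.S) - 1).max() < 1e-10

    def test_condensed_equals_direct_summed_orbital(self, ethane,
                                                    ethane_integrals,
                                                    gauss_oracle):
        """Condensation must equal integrals over the explicit normalized sum."""
        groups = list(bond_split(ethane, 0))
        cond, orbs = condense_integrals(ethane_integrals, groups)
        raw = vertex_orbitals(ethane, order=3)
        summed = [gauss_oracle.GFunction.summed([raw[i] for i in grp], o.norm)
                  for grp, o in zip(groups, orbs)]
        nuclei_pos = [ethane.vertices[i].position for i in ethane.nuclei]
        for a in range(2):
            for b in range(2):
                assert cond.S[a, b] == pytest.approx(
                    gauss_oracle.overlap(summed[a], summed[b]), abs=1e-10)
                assert cond.K[a, b] == pytest.approx(
                    gauss_oracle.kinetic(summed[a], summed[b]), abs=1e-10)
                for c, pos in enumerate(nuclei_pos):
                    assert cond.U[a, b, c] == pytest.approx(
                        gauss_oracle.attraction(summed[a], summed[b], pos),
                        abs=1e-10)
        assert cond.R[0, 1, 0, 1] == pytest.approx(
            gauss_oracle.eri(summed[0], summed[1], summed[0], summed[1]),
            abs=1e-10)
        assert cond.R[0, 0, 1, 1] == pytest.approx(
            gauss_oracle.eri(summed[0], summed[0], summed[1], summed[1]),
            abs=1e-10)

    def test_recursion_consistency(self, gauss_oracle):
        """Two-level condensation equals one-shot condensation with the
        composite weights (associativity of the normalized double sums).

        A level-2 recursion orbital is a renormalized sum of level-1
        recursion orbitals, hence a *weighted* sum of anchors with weight
        N_level2 · N_level1(group); condensing the anchors in one shot with
        exactly those weights must reproduce the level-2 blocks, and the
        level-2 blocks must equal direct integrals over the explicitly
        expanded weighted orbital.
        """
        from chemion.condense import aggregation_matrix
        g = build_chain(2, "CH3", [0.3, 1.2])
        aset = build_anchor_integrals(g, order=3)
        fine = [[0], [1, 3, 4], [2, 6, 7], [5, 8, 9, 10]]
        level1, orbs1 = condense_integrals(aset, fine)
        level2, orbs2 = condense_integrals(level1, [[0, 1], [2, 3]], level=2)
        T1 = aggregation_matrix(fine, aset.S)
        T2 = aggregation_matrix([[0, 1], [2, 3]], level1.S)
        T = T1 @ T2  # composite anchor → level-2 aggregation
        assert np.abs(level2.S - T.T @ aset.S @ T).max() < 1e-12
        assert np.abs(level2.K - T.T @ aset.K @ T).max() < 1e-12
        assert np.abs(level2.R - np.einsum("pa,qb,rc,sd,pqrs->abcd",
                                           T, T, T, T, aset.R)).max() < 1e-12
        # and against the independent summed-orbital oracle
        raw = vertex_orbitals(g, order=3)
        summed = []
        for col in range(2):
            funcs, scales = [], []
            for p in range(g.n_vtx):
                if T[p, col] != 0.0:
                    funcs.append(raw[p])
                    scales.append(T[p, col])
            parts = [gauss_oracle.GFunction.summed([f], s)
                     for f, s in zip(funcs, scales)]
            alphas = np.concatenate([p.alphas for p in parts])
            coeffs = np.concatenate([p.coeffs for p in parts])
            centers = np.concatenate([p.centers for p in parts])
            summed.append(gauss_oracle.GFunction(alphas, coeffs, centers))
        for a in range(2):
            for b in range(2):
                assert level2.S[a, b] == pytest.approx(
                    gauss_oracle.overlap(summed[a], summed[b]), abs=1e-10)

    def test_overlapping_groups_rejected(self, methane_integrals):
        with pytest.raises(CondensationError):
            condense_integrals(methane_integrals, [[0, 1], [1, 2]])


class TestOneChemionMatrix:
    def test_zero_charges(self, methane_integrals):
        z = np.zeros(methane_integrals.U.shape[2])
        V, H = one_chemion_matrix(methane_integrals.K, methane_integrals.U, z)
        assert np.abs(V).max() == 0
        assert np.abs(H - methane_integrals.K).max() == 0

    def test_linearity_in_charges(self, methane_integrals, methane):
        ens = full_molecule_ensemble(methane)
        V1, _ = one_chemion_matrix(methane_integrals.K, methane_integrals.U,
                                   ens.z_prop)
        V2, _ = one_chemion_matrix(methane_integrals.K, methane_integrals.U,
                                   2 * ens.z_prop)
        assert np.abs(V2 - 2 * V1).max() < 1e-12

    def test_against_elementwise_loop(self, methane_integrals, methane):
        ens = full_molecule_ensemble(methane)
        V, H = one_chemion_matrix(methane_integrals.K, methane_integrals.U,
                                  ens.z_prop)
        nv = methane_integrals.n_vtx
        for m in range(nv):
            for n in range(nv):
                v_ref = sum(ens.z_prop[c] * methane_integrals.U[m, n, c]
                            for c in range(len(ens.z_prop)))
                assert V[m, n] == pytest.approx(v_ref, abs=1e-12)
                assert H[m, n] == pytest.approx(
                    methane_integrals.K[m, n] - v_ref, abs=1e-12)
        assert np.abs(H - H.T).max() < 1e-10


class TestFockCondensation:
    def test_first_branch_equals_second_branch(self, ethane, ethane_integrals):
        """Condensing a precursor Fock block equals rebuilding it from the
        condensed H, R and the matching condensed density."""
        groups = list(bond_split(ethane, 0))
        cond, orbs = condense_integrals(ethane_integrals, groups)
        ens = chain_bond_ensemble(ethane, 0)
        state = scf(cond, ens, scf_tol=1e-10)
        assert state.converged
        # expand the condensed density to the vertex basis and rebuild there
        from chemion.condense import aggregation_matrix, one_chemion_matrix
        T = aggregation_matrix(groups, ethane_integrals.S)
        D_full = T @ state.D @ T.T
        _, H_full = one_chemion_matrix(ethane_integrals.K, ethane_integrals.U,
                                       ens.z_prop)
        F_full = build_fock(H_full, ethane_integrals.R, D_full)
        F_cond = condense_fock_block(F_full, groups, ethane_integrals.S)
        assert np.abs(F_cond - state.F).max() < 1e-8

    def test_bank_reuse_and_not_available(self, tmp_path, methane,
                                          methane_integrals):
        bank = FragmentBank(tmp_path / "bank.h5")
        key = fragment_key(methane, level=0, ensemble_kind="full-molecule",
                           order=4)
        assert condense_fock(bank, key) is None  # missing → "not available"
        ens = full_molecule_ensemble(methane)
        state = scf(methane_integrals, ens, scf_tol=1e-8, damping=0.3,
                    max_iter=300)
        bank.store(key, {"F": state.F, "S": state.S})
        # singleton condensation reproduces the stored block exactly
        got = condense_fock(bank, key)
        assert np.array_equal(got, state.F)
        # a different geometry hash is a different key: never silently reused
        other = set_torsion(build_chain(1, "CH3"), 0, 0.7)
        key2 = fragment_key(other, level=0, ensemble_kind="full-molecule",
                            order=4)
        assert key2 != key
        assert condense_fock(bank, key2) is None


class TestFragmentBank:
    def test_round_trip_idempotent(self, tmp_path, methane_integrals):
        bank = FragmentBank(tmp_path / "bank.h5")
        blocks = {"S": methane_integrals.S, "R": methane_integrals.R}
        bank.store("key", blocks, attrs={"mode": "exact"})
        first = bank.load("key")
        bank.store("key", first.blocks, attrs=first.attrs)
        second = bank.load("key")
        for name in blocks:
            assert np.array_equal(first.blocks[name], second.blocks[name])
            assert np.array_equal(first.blocks[name], blocks[name])
        assert first.attrs["mode"] == "exact"

    def test_geometry_hash_is_rigid_motion_invariant(self, methane):
        from scipy.spatial.transform import Rotation
        h1 = geometry_hash(methane)
        g2 = methane.copy()
        rot = Rotation.from_rotvec([0.2, 0.4, -0.3])
        for v in g2.vertices:
            v.position = rot.apply(v.position) + 1.5
        assert geometry_hash(g2) == h1

    def test_torsion_changes_the_key(self, ethane):
        k1 = fragment_key(ethane, torsion=0.0)
        k2 = fragment_key(ethane, torsion=0.1)
        assert k1 != k2


class TestIntegralBudget:
    def test_anchor_counts(self):
        c = integral_budget("anchor")
        assert (c["S"], c["K"], c["U_bound"], c["R"]) == (25, 25, 125, 625)

    @pytest.mark.parametrize("n,s,r", [(0, 8 ** 2 - 4 ** 2, 8 ** 4 - 4 ** 4),
                                       (1, 11 ** 2 - 7 ** 2, 11 ** 4 - 7 ** 4),
                                       (2, 14 ** 2 - 10 ** 2, 14 ** 4 - 10 ** 4),
                                       (4, 20 ** 2 - 16 ** 2, 20 ** 4 - 16 ** 4)])
    def test_prolongation_counts(self, n, s, r):
        c = integral_budget(n)
        assert c["S"] == c["K"] == s
        assert c["R"] == r
        assert c["U_bound"] == c["a"] ** 3 - c["b"] ** 3

    def test_difference_of_powers_factorizations(self):
        for n in range(8):
            c = integral_budget(n)
            a, b = c["a"], c["b"]
            assert a - b == 4
            assert c["S"] == (a - b) * (a + b)
            assert c["U_bound"] == (a - b) * (a * a + a * b + b * b)
            assert c["R"] == (a - b) * (a ** 3 + a ** 2 * b + a * b ** 2 + b ** 3)
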