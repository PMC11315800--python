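"""Topology, geometry, torsions, ensembles and proportional charges."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from chemion import constants
from chemion.molecule import (GeometryError, TopologyError, bond_split,
                              build_chain, build_diatomic, build_monofocal,
                              chain_bond_ensemble, euler_counts,
                              full_molecule_ensemble,
                              functional_group_partition, get_torsion,
                              nuclear_repulsion, proportional_charges,
                              set_torsion)

ALL_ELEMENTS = ("C", "N", "O", "F", "Si", "P", "S", "Cl")
ALL_TERMINALS = ("CH3", "NH2", "OH", "F", "SiH3", "PH2", "SH", "Cl")


class TestMonofocals:
    @pytest.mark.parametrize("element,n_h,n_love", [
        ("C", 4, 0), ("N", 3, 1), ("O", 2, 2), ("F", 1, 3),
        ("Si", 4, 0), ("P", 3, 1), ("S", 2, 2), ("Cl", 1, 3),
    ])
    def test_counts_and_composition(self, element, n_h, n_love):
        g = build_monofocal(element)
        nv, nchp, nnuc = euler_counts(g)
        assert (nv, nchp) == (5, 4)
        assert nnuc == 1 + n_h
        kinds = [v.kind for v in g.vertices]
        assert kinds.count("hydrogen-ligand") == n_h
        assert kinds.count("lone-pair") == n_love

    def test_lone_pairs_sit_one_bohr_from_parent(self):
        g = build_monofocal("F")
        center = g.vertices[0].position
        for v in g.vertices:
            if v.kind == "lone-pair":
                assert np.linalg.norm(v.position - center) == pytest.approx(
                    constants.LONE_PAIR_DISTANCE, abs=1e-12)

    def test_lone_pairs_carry_no_nucleus(self, water):
        assert euler_counts(water) == (5, 4, 3)
        assert all(water.vertices[i].kind != "lone-pair" for i in water.nuclei)

    def test_unknown_element_rejected(self):
        with pytest.raises(TopologyError):
            build_monofocal("He")

    def test_valence_shell_follows_periodic_row(self):
        for el in ALL_ELEMENTS:
            g = build_monofocal(el)
            assert g.vertices[0].n_val == (2 if el in "CNOF" else 3)
            assert g.vertices[0].zeta == pytest.approx(
                g.vertices[0].z_val / g.vertices[0].n_val)
            for v in g.vertices:
                if v.kind == "lone-pair":
                    assert v.n_val == g.vertices[0].n_val


class TestChains:
    @pytest.mark.parametrize("n", range(7))
    @pytest.mark.parametrize("terminal", ALL_TERMINALS)
    def test_euler_rule_exhaustive(self, n, terminal):
        g = build_chain(n, terminal, [0.3] * n)
        nv, nchp, _ = euler_counts(g)
        assert nv == 3 * n + 5
        assert nv == nchp + 1

    def test_errors(self):
        with pytest.raises(TopologyError):
            build_chain(-1, "CH3")
        with pytest.raises(TopologyError):
            build_chain(1, "BH2")
        with pytest.raises(TopologyError):
            build_chain(2, "CH3", [0.1])

    def test_functional_group_chart_has_n_plus_2_vertices(self):
        for n in (0, 1, 2, 3):
            g = build_chain(n, "CH3", [0.2] * n)
            groups = functional_group_partition(g)
            assert len(groups) == n + 2
            assert sorted(i for grp in groups for i in grp) == list(range(g.n_vtx))

    def test_two_vertex_chart_of_chain_bond(self, ethane):
        prox, dist = bond_split(ethane, 0)
        assert len(prox) == 4  # H3C: methyl carbon + 3 hydrogens
        assert len(dist) == 4  # XV3 terminal
        nuc_prox = [i for i in prox if ethane.vertices[i].kind != "lone-pair"]
        assert len(nuc_prox) == 4

    def test_second_vertex_nuclei_grow_by_three(self):
        # #nuc of the distal fragment: 4, 7, 10 for growing all-carbon chains
        for m, expected in ((1, 4), (2, 7), (3, 10)):
            g = build_chain(m, "CH3", [0.0] * m)
            _, dist = bond_split(g, 0)
            nuc = [i for i in dist if g.vertices[i].kind != "lone-pair"]
            assert len(nuc) == expected


class TestGeometry:
    def test_tetrahedron_angle(self):
        assert math.degrees(constants.TETRA_ANGLE) == pytest.approx(109.471, abs=1e-3)
        assert math.degrees(constants.DIHEDRAL_ANGLE) == pytest.approx(120.0, abs=1e-12)

    def test_bond_angles_are_tetrahedral(self, methane):
        c = methane.vertices[0].position
        dirs = [v.position - c for v in methane.vertices[1:]]
        for a, b in itertools.combinations(dirs, 2):
            cos = a @ b / np.linalg.norm(a) / np.linalg.norm(b)
            assert cos == pytest.approx(-1.0 / 3.0, abs=1e-12)

    def test_bond_length_table_override(self):
        g = build_chain(1, "CH3", [0.0], bond_lengths={("C", "C"): 1.60})
        c1 = g.vertices[g.meta["heavy_idx"][0]].position
        c2 = g.vertices[g.meta["heavy_idx"][1]].position
        assert np.linalg.norm(c1 - c2) * constants.BOHR_ANGSTROM == pytest.approx(1.60)


class TestTorsions:
    def test_two_pi_periodicity(self, ethane):
        a = set_torsion(ethane, 0, 0.0)
        b = set_torsion(a, 0, 2.0 * math.pi)
        assert np.abs(a.positions - b.positions).max() < 1e-12

    def test_rigid_rotation_preserves_all_distances(self, ethane):
        g2 = set_torsion(ethane, 0, 1.234)
        _, dist = bond_split(ethane, 0)
        p1, p2 = ethane.positions, g2.positions
        for i, j in itertools.combinations(dist, 2):
            assert np.linalg.norm(p1[i] - p1[j]) == pytest.approx(
                np.linalg.norm(p2[i] - p2[j]), abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(t1=st.floats(0, 2 * math.pi - 1e-9), t2=st.floats(0, 2 * math.pi - 1e-9))
    def test_group_action(self, t1, t2):
        g = build_chain(1, "CH3")
        via_two = set_torsion(set_torsion(g, 0, t1), 0, t2)
        direct = set_torsion(g, 0, t2)
        assert np.abs(via_two.positions - direct.positions).max() < 1e-10

    def test_readback(self):
        g = build_chain(2, "OH", [0.4, 1.1])
        assert get_torsion(g, 0) == pytest.approx(0.4, abs=1e-10)
        assert get_torsion(g, 1) == pytest.approx(1.1, abs=1e-10)

    def test_threefold_congruence_by_relabeling(self, ethane):
        """τ and τ+2π/3 give superposable ethane geometries.

        Brute-force oracle: minimize RMSD over all permutations of the three
        distal hydrogens.
        """
        g1 = set_torsion(ethane, 0, 0.4)
        g2 = set_torsion(ethane, 0, 0.4 + 2 * math.pi / 3)
        _, dist = bond_split(ethane, 0)
        h_dist = [i for i in dist if ethane.vertices[i].kind == "hydrogen-ligand"]
        fixed = [i for i in range(ethane.n_vtx) if i not in h_dist]
        best = np.inf
        for perm in itertools.permutations(h_dist):
            order = fixed + list(perm)
            ref = fixed + h_dist
            rmsd = np.sqrt(np.mean((g1.positions[ref] - g2.positions[order]) ** 2))
            best = min(best, rmsd)
        assert best < 1e-10

    def test_invalid_index(self, ethane):
        with pytest.raises(TopologyError):
            set_torsion(ethane, 5, 0.0)


class TestEnsembles:
    def test_ethane_bond_charges(self, ethane):
        ens = chain_bond_ensemble(ethane, 0)
        assert ens.chp == 1
        by_element = {ethane.vertices[i].element: ens.z_prop[k]
                      for k, i in enumerate(ethane.nuclei)}
        assert by_element["C"] == pytest.approx(4.0 / 7.0, abs=1e-12)
        assert by_element["H"] == pytest.approx(1.0 / 7.0, abs=1e-12)

    def test_methane_full_ensemble_is_unscaled(self, methane):
        ens = full_molecule_ensemble(methane)
        assert ens.chp == 4
        z_val = [methane.vertices[i].z_val for i in methane.nuclei]
        assert np.allclose(ens.z_prop, z_val, atol=1e-12)

    @pytest.mark.parametrize("terminal", ALL_TERMINALS)
    def test_normalization_identity(self, terminal):
        g = build_chain(1, terminal, [0.0])
        for chp in (1, 2, 5):
            z = proportional_charges(chp, g)
            assert z.sum() == pytest.approx(2.0 * chp, abs=1e-12)

    def test_zero_chp_rejected(self, methane):
        with pytest.raises(ValueError):
            proportional_charges(0, methane)


class TestNuclearRepulsion:
    def test_two_unit_charges(self):
        g = build_diatomic("F", "Cl")
        ens = chain_bond_ensemble(g, 0)
        # independent brute-force double loop
        nuc = g.nuclei
        brute = 0.0
        for a in range(len(nuc)):
            for b in range(a + 1, len(nuc)):
                d = np.linalg.norm(g.vertices[nuc[a]].position
                                   - g.vertices[nuc[b]].position)
                brute += ens.z_prop[a] * ens.z_prop[b] / d
        assert nuclear_repulsion(ens, g) == pytest.approx(brute, abs=1e-12)

    def test_methane_against_brute_force(self, methane):
        ens = full_molecule_ensemble(methane)
        pos = [methane.vertices[i].position for i in methane.nuclei]
        brute = sum(ens.z_prop[a] * ens.z_prop[b] / np.linalg.norm(pos[a] - pos[b])
                    for a in range(len(pos)) for b in range(a + 1, len(pos)))
        assert nuclear_repulsion(ens, methane) == pytest.approx(brute, abs=1e-12)

    def test_rigid_motion_invariance(self, methane):
        ens = full_molecule_ensemble(methane)
        e0 = nuclear_repulsion(ens, methane)
        g2 = methane.copy()
        rot = Rotation.from_rotvec([0.4, -1.1, 0.2])
        for v in g2.vertices:
            v.position = rot.apply(v.position) + np.array([3.0, -1.0, 0.5])
        assert nuclear_repulsion(ens, g2) == pytest.approx(e0, abs=1e-12)

    def test_coincident_nuclei_rejected(self, methane):
        ens = full_molecule_ensemble(methane)
        g2 = methane.copy()
        g2.vertices[1].position = g2.vertices[2].position.copy()
        with pytest.raises(GeometryError):
            nuclear_repulsion(ens, g2)
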