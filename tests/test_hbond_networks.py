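"""Protonation geometry, Baker–Hubbard detection, and network partitioning."""

import math

import networkx as nx
import numpy as np
import pytest

from foldkit import (HBondParams, build_networks, detect_hbonds, find_networks,
                     parse_structure, protonate)
from foldkit.fixtures import make_chain, make_hbond_triple, make_pair

from conftest import random_rigid_transform


def angle(a, b, c):
    v1, v2 = a - b, c - b
    return math.degrees(math.acos(
        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))


class TestProtonation:
    def test_serine_gets_one_hydroxyl_hydrogen(self):
        structure = protonate(parse_structure(make_chain(["SER"])))
        hydrogens = [a for a in structure.atoms if a.element == "H"]
        assert len(hydrogens) == 1
        og = structure.residues[0].atom("OG")
        assert np.linalg.norm(hydrogens[0].coords - og.coords) == pytest.approx(0.96, abs=0.01)

    def test_aspartate_carboxylate_unprotonated(self):
        structure = protonate(parse_structure(make_chain(["ASP"])))
        assert sum(a.element == "H" for a in structure.atoms) == 0

    def test_lysine_ammonium_geometry(self):
        structure = protonate(parse_structure(make_chain(["LYS"])))
        hydrogens = [a for a in structure.atoms if a.element == "H"]
        assert len(hydrogens) == 3
        nz = structure.residues[0].atom("NZ").coords
        for i in range(3):
            assert np.linalg.norm(hydrogens[i].coords - nz) == pytest.approx(1.01, abs=0.01)
            for j in range(i + 1, 3):
                assert angle(hydrogens[i].coords, nz, hydrogens[j].coords) == pytest.approx(
                    109.5, abs=5.0)

    @pytest.mark.parametrize("res_name,n_h", [
        ("ARG", 5), ("ASN", 2), ("GLN", 2), ("TRP", 1), ("HIS", 1),
        ("TYR", 1), ("THR", 1), ("GLU", 0), ("ALA", 0),
    ])
    def test_fixed_ph7_proton_counts(self, res_name, n_h):
        structure = protonate(parse_structure(make_chain([res_name])))
        assert sum(a.element == "H" for a in structure.atoms) == n_h

    def test_existing_hydrogens_kept(self):
        structure = parse_structure(make_hbond_triple(2.0, 180.0))
        protonated = protonate(structure)
        donors_h = [a for a in protonated.atoms if a.element == "H"
                    and a.res_seq == 1]
        assert len(donors_h) == 1  # pre-placed HG retained, not duplicated
        original = [a for a in structure.atoms if a.element == "H"][0]
        np.testing.assert_allclose(donors_h[0].coords, original.coords, atol=1e-6)

    def test_hydroxyl_points_at_nearby_acceptor(self):
        structure = parse_structure(
            make_pair("SER", "ASP", 2.8, contact_atom_a="OG", contact_atom_b="OD1"))
        protonated = protonate(structure)
        h = [a for a in protonated.atoms if a.element == "H"][0]
        og = protonated.residues[0].atom("OG").coords
        od1 = protonated.residues[1].atom("OD1").coords
        # the placed H must be closer to the acceptor than the hydroxyl oxygen is
        assert np.linalg.norm(h.coords - od1) < np.linalg.norm(og - od1)


class TestDetection:
    def test_ideal_collinear_bond_found(self):
        structure = parse_structure(make_hbond_triple(d=2.0, theta=180.0))
        bonds = detect_hbonds(structure)
        assert len(bonds) == 1
        assert bonds[0].d == pytest.approx(2.0, abs=1e-3)
        assert bonds[0].theta == pytest.approx(180.0, abs=0.5)

    def test_angle_below_cutoff_rejected(self):
        structure = parse_structure(make_hbond_triple(d=2.0, theta=110.0))
        assert detect_hbonds(structure) == []

    def test_distance_beyond_cutoff_rejected(self):
        structure = parse_structure(make_hbond_triple(d=2.6, theta=180.0))
        assert detect_hbonds(structure) == []

    def test_unprotonated_structure_rejected(self):
        structure = parse_structure(make_chain(["SER", "ASP"]))
        with pytest.raises(ValueError, match="protonate"):
            detect_hbonds(structure)

    def test_bonds_satisfy_their_own_cutoffs(self):
        structure = parse_structure(
            make_pair("SER", "ASP", 2.8, contact_atom_a="OG", contact_atom_b="OD1"))
        params = HBondParams()
        _, bonds, protonated = find_networks(structure, params)
        assert bonds
        for b in bonds:
            assert b.d < params.d_max
            assert b.theta > params.theta_min
            d = np.linalg.norm(b.hydrogen.coords - b.acceptor.coords)
            assert d == pytest.approx(b.d)
            assert angle(b.donor.coords, b.hydrogen.coords, b.acceptor.coords) == \
                pytest.approx(b.theta, abs=1e-6)

    def test_widening_cutoffs_never_removes_bonds(self):
        structure = protonate(parse_structure(
            make_pair("SER", "ASP", 2.8, contact_atom_a="OG", contact_atom_b="OD1")))
        narrow = detect_hbonds(structure, HBondParams(theta_min=130.0, d_max=2.2))
        wide = detect_hbonds(structure, HBondParams(theta_min=110.0, d_max=2.6))
        key = lambda b: (b.hydrogen.serial, b.acceptor.serial)
        assert {key(b) for b in narrow} <= {key(b) for b in wide}

    def test_detection_invariant_under_rigid_transform(self):
        structure = protonate(parse_structure(
            make_pair("SER", "ASP", 2.8, contact_atom_a="OG", contact_atom_b="OD1")))
        rng = np.random.default_rng(17)
        rot, trans = random_rigid_transform(rng)
        moved = structure.transformed(rot, trans)
        key = lambda b: (b.hydrogen.serial, b.acceptor.serial)
        assert {key(b) for b in detect_hbonds(structure)} == \
            {key(b) for b in detect_hbonds(moved)}


class TestAgainstMdtraj:
    def test_detection_matches_baker_hubbard_oracle(self, small_protein, tmp_path):
        """Bond set equals mdtraj's baker_hubbard (same ϑ/d criterion) on the
        identical protonated coordinates."""
        import mdtraj as md

        from foldkit import parse_structure, write_pdb

        path = tmp_path / "protonated.pdb"
        write_pdb(protonate(small_protein), path)
        reparsed = parse_structure(path.read_text())  # same rounded coords
        ours = {(b.donor.res_seq, b.donor.name, b.acceptor.res_seq, b.acceptor.name)
                for b in detect_hbonds(reparsed)}
        traj = md.load(str(path))
        top = traj.topology
        theirs = set()
        for d, h, a in md.baker_hubbard(traj, freq=0.0, sidechain_only=True,
                                        periodic=False):
            theirs.add((top.atom(d).residue.resSeq, top.atom(d).name,
                        top.atom(a).residue.resSeq, top.atom(a).name))
        assert ours == theirs


class TestNetworks:
    def test_path_connected_residues_share_a_network(self):
        structure = parse_structure(make_hbond_triple(2.0, 180.0))
        bonds = detect_hbonds(structure)
        partition = build_networks(bonds, structure)
        assert len(partition) == 1
        members, _ = partition[0]
        assert len(members) == 2

    def test_no_bonds_no_networks(self):
        assert len(build_networks([])) == 0

    def test_partition_matches_networkx_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n_res = 20
            n_bonds = int(rng.integers(0, 30))
            pairs = set()
            while len(pairs) < n_bonds:
                i, j = sorted(rng.integers(1, n_res + 1, size=2))
                if i != j:
                    pairs.add((int(i), int(j)))
            structure = parse_structure(make_chain(["SER"] * n_res))
            res = {r.res_seq: r for r in structure.residues}
            bonds = []
            for i, j in sorted(pairs):
                donor = res[i].atom("OG")
                acceptor = res[j].atom("OG")
                h = donor  # geometry is irrelevant for partitioning
                from foldkit.hbond_networks import HBond
                bonds.append(HBond(donor=donor, hydrogen=h, acceptor=acceptor,
                                   d=2.0, theta=150.0))
            partition = build_networks(bonds, structure)
            g = nx.Graph()
            g.add_edges_from(pairs)
            expected = sorted(tuple(sorted(c)) for c in nx.connected_components(g))
            got = sorted(tuple(sorted(r.res_seq for r in members))
                         for members, _ in partition)
            assert got == expected

    def test_networks_ordered_by_size(self):
        structure = parse_structure(make_chain(["SER"] * 6))
        res = {r.res_seq: r for r in structure.residues}
        from foldkit.hbond_networks import HBond
        mk = lambda i, j: HBond(res[i].atom("OG"), res[i].atom("OG"),
                                res[j].atom("OG"), 2.0, 150.0)
        partition = build_networks([mk(1, 2), mk(3, 4), mk(4, 5)], structure)
        assert [len(m) for m, _ in partition] == [3, 2]
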