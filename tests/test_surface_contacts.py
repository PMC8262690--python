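"""Section-based contact areas: grid, candidacy, ownership, oracles."""

import math

import numpy as np
import pytest

from foldkit import (ContactParams, RadiusTable, contact_areas, fibonacci_grid,
                     neighbor_candidates, parse_structure)
from foldkit.surface_contacts import assign_sections
from foldkit.fixtures import make_pair

from conftest import random_rigid_transform

R_EXT = 1.88 + 1.4  # solvent-extended carbon radius


class TestFibonacciGrid:
    def test_directions_are_unit_and_fraction_is_one_over_n(self):
        grid = fibonacci_grid(610)
        norms = np.linalg.norm(grid.directions, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        assert grid.section_area_fraction == pytest.approx(1 / 610)
        assert grid.section_area_fraction == pytest.approx(0.0016, abs=5e-5)

    def test_lattice_is_balanced(self):
        com = fibonacci_grid(200).directions.mean(axis=0)
        assert np.linalg.norm(com) < 0.05

    def test_too_few_sections_rejected(self):
        with pytest.raises(ValueError):
            fibonacci_grid(11)


class TestCandidacy:
    @pytest.mark.parametrize("separation,expected", [(6.50, True), (6.60, False)])
    def test_carbon_carbon_cutoff(self, leu_pair_factory, separation, expected):
        """Two carbons are contact candidates iff within 2×(1.88+1.4) = 6.56 Å."""
        structure = leu_pair_factory(separation)
        # the fixture's closest pair are both carbons
        candidates = set()
        for atom in structure.residues[0].heavy_atoms():
            for b in neighbor_candidates(structure, atom):
                candidates.add(b.serial)
        assert bool(candidates) is expected

    def test_own_residue_and_self_excluded(self, leu_pair_factory):
        structure = leu_pair_factory(4.0)
        atom = structure.residues[0].heavy_atoms()[0]
        neighbors = neighbor_candidates(structure, atom)
        assert all(b.serial != atom.serial for b in neighbors)
        assert all(b.res_seq != atom.res_seq for b in neighbors)


class TestOwnership:
    def test_no_neighbors_means_no_owners(self):
        grid = fibonacci_grid(610)
        owners = assign_sections(np.zeros(3), R_EXT, np.zeros((0, 3)),
                                 np.zeros(0), np.zeros(0, dtype=int), grid)
        assert (owners == -1).all()

    def test_engulfing_neighbor_owns_everything(self):
        grid = fibonacci_grid(610)
        owners = assign_sections(np.zeros(3), R_EXT, np.array([[0.1, 0, 0]]),
                                 np.array([50.0]), np.array([7]), grid)
        assert (owners == 0).all()

    def test_closest_claimant_wins(self):
        """Sections claimed by both neighbors go to the one nearer the center."""
        grid = fibonacci_grid(610)
        centers = np.array([[4.0, 0, 0], [3.0, 0, 0]])
        owners = assign_sections(np.zeros(3), R_EXT, centers,
                                 np.array([R_EXT, R_EXT]), np.array([5, 9]), grid)
        # every section the far neighbor could claim is also claimable by the
        # near one (same axis, larger overlap), so the far neighbor gets none
        assert (owners != 0).all()
        assert (owners == 1).any()

    def test_serial_breaks_exact_ties(self):
        grid = fibonacci_grid(610)
        centers = np.array([[4.0, 0, 0], [4.0, 0, 0]])
        owners = assign_sections(np.zeros(3), R_EXT, centers,
                                 np.array([R_EXT, R_EXT]), np.array([9, 5]), grid)
        claimed = owners[owners >= 0]
        assert claimed.size and (claimed == 1).all()  # index 1 has serial 5

    def test_area_conservation_is_exact(self):
        """Owned plus unowned section areas sum to the full sphere area."""
        grid = fibonacci_grid(610)
        owners = assign_sections(np.zeros(3), R_EXT, np.array([[4.0, 0, 0]]),
                                 np.array([R_EXT]), np.array([2]), grid)
        per_section = 4 * math.pi * R_EXT ** 2 / grid.n
        total = (owners >= 0).sum() * per_section + (owners < 0).sum() * per_section
        assert total == pytest.approx(4 * math.pi * R_EXT ** 2, rel=1e-12)


def analytic_cap_area(d, r_a, r_b):
    """Exact area of the contact region on A's extended sphere.

    A probe at P (|P − cA| = r_a) penetrates B iff |P − cB| ≤ r_b; by the law
    of cosines the region is the spherical cap cos θ ≥ (r_a² + d² − r_b²)/(2·r_a·d).
    """
    cos_t = (r_a ** 2 + d ** 2 - r_b ** 2) / (2 * r_a * d)
    cos_t = min(1.0, max(-1.0, cos_t))
    return 2 * math.pi * r_a ** 2 * (1 - cos_t)


class TestAreasAgainstOracles:
    @pytest.mark.parametrize("d", [3.0, 4.0, 5.0, 6.0])
    def test_monte_carlo_oracle_single_neighbor(self, d):
        """Default-grid areas match a 10⁵-direction random oracle within 3%."""
        rng = np.random.default_rng(20240601)
        grid = fibonacci_grid(610)
        owners = assign_sections(np.zeros(3), R_EXT, np.array([[d, 0, 0]]),
                                 np.array([R_EXT]), np.array([2]), grid)
        area = (owners >= 0).sum() * 4 * math.pi * R_EXT ** 2 / grid.n
        u = rng.normal(size=(400_000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        hit = np.linalg.norm(R_EXT * u - np.array([d, 0, 0]), axis=1) <= R_EXT
        oracle = 4 * math.pi * R_EXT ** 2 * hit.mean()
        assert area == pytest.approx(oracle, rel=0.03)

    @pytest.mark.parametrize("d", [3.0, 4.5, 6.0, 6.5])
    def test_analytic_cap_oracle(self, d):
        """Refined-grid areas match the closed-form spherical cap within 1%."""
        grid = fibonacci_grid(61000)
        owners = assign_sections(np.zeros(3), R_EXT, np.array([[d, 0, 0]]),
                                 np.array([R_EXT]), np.array([2]), grid)
        area = (owners >= 0).sum() * 4 * math.pi * R_EXT ** 2 / grid.n
        assert area == pytest.approx(analytic_cap_area(d, R_EXT, R_EXT), rel=0.01)

    def test_directed_areas_symmetric_for_identical_residues(self, leu_pair_factory):
        structure = leu_pair_factory(4.0)
        matrix = contact_areas(structure, structure.residues)
        assert matrix.directed[0, 1] == pytest.approx(matrix.directed[1, 0], rel=0.05)
        assert matrix.areas[0, 1] == pytest.approx(matrix.directed[0, 1]
                                                   + matrix.directed[1, 0])

    def test_far_pair_has_zero_area(self, leu_pair_factory):
        structure = leu_pair_factory(20.0)
        matrix = contact_areas(structure, structure.residues)
        assert matrix.areas.sum() == 0.0

    def test_matrix_invariants(self, small_protein):
        matrix = contact_areas(small_protein, small_protein.residues)
        assert (matrix.areas >= 0).all()
        np.testing.assert_allclose(matrix.areas, matrix.areas.T)
        assert (np.diag(matrix.areas) == 0).all()

    def test_empty_selection_rejected(self, small_protein):
        with pytest.raises(ValueError):
            contact_areas(small_protein, [])


class TestParameterEffects:
    def test_enlarging_neighbor_radius_never_shrinks_its_area(self):
        grid = fibonacci_grid(610)
        areas = []
        for r_b in (2.8, 3.0, 3.28, 3.6, 4.0):
            owners = assign_sections(np.zeros(3), R_EXT, np.array([[5.0, 0, 0]]),
                                     np.array([r_b]), np.array([2]), grid)
            areas.append((owners == 0).sum())
        assert all(b >= a for a, b in zip(areas, areas[1:]))

    def test_grid_refinement_agrees(self, leu_pair_factory):
        """Residue-pair areas at n=610 and n=6100 agree within 5%."""
        structure = leu_pair_factory(4.0)
        coarse = contact_areas(structure, structure.residues,
                               ContactParams(n_sections=610))
        fine = contact_areas(structure, structure.residues,
                             ContactParams(n_sections=6100))
        assert coarse.areas[0, 1] == pytest.approx(fine.areas[0, 1], rel=0.05)

    def test_vdw_area_sphere_scales_down(self, leu_pair_factory):
        structure = leu_pair_factory(4.0)
        ext = contact_areas(structure, structure.residues,
                            ContactParams(area_sphere="solvent-extended"))
        bare = contact_areas(structure, structure.residues,
                             ContactParams(area_sphere="van-der-waals"))
        assert 0 < bare.areas[0, 1] < ext.areas[0, 1]

    def test_rigid_transform_invariance(self, small_protein):
        rng = np.random.default_rng(5)
        rot, trans = random_rigid_transform(rng)
        moved = small_protein.transformed(rot, trans)
        a = contact_areas(small_protein, small_protein.residues).areas
        b = contact_areas(moved, moved.residues).areas
        np.testing.assert_allclose(a, b, atol=1e-9)
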