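"""Atomic contact areas by the contacts-of-structural-units (CSU) section method.

Each heavy atom is a sphere of fixed van der Waals radius.  The solvent-
extended sphere (vdW radius + 1.4 Å water probe) is discretized into n
near-uniform sections with a Fibonacci lattice; a section represents a probe
position on the atom's surface.  A section is in contact with a neighboring
atom when the probe placed there penetrates the neighbor's solvent-extended
sphere, and when several neighbors are penetrated the section belongs to the
one whose center is closest to the center of the original atom.  Summing
section areas over atoms yields a residue-against-residue contact-area matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, RadiusTable, Residue, Structure

__all__ = [
    "ContactParams",
    "SectionGrid",
    "ContactAreaMatrix",
    "fibonacci_grid",
    "neighbor_candidates",
    "assign_sections",
    "contact_areas",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class ContactParams:
    n_sections: int = 610
    probe_radius: float = 1.4
    #: which sphere's area a section carries: the solvent-extended sphere
    #: (radius r + probe, the sphere the sections actually live on) or the
    #: bare van der Waals sphere.
    area_sphere: Literal["solvent-extended", "van-der-waals"] = "solvent-extended"
    #: whether all heavy atoms of the structure compete for sections, or only
    #: atoms of the selected residues.
    occluder_scope: Literal["all-heavy-atoms", "selection-only"] = "all-heavy-atoms"

    def __post_init__(self) -> None:
        if self.n_sections < 12:
            raise ValueError("n_sections must be at least 12")
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.area_sphere not in ("solvent-extended", "van-der-waals"):
            raise ValueError(f"unknown area_sphere {self.area_sphere!r}")
        if self.occluder_scope not in ("all-heavy-atoms", "selection-only"):
            raise ValueError(f"unknown occluder_scope {self.occluder_scope!r}")


@dataclass
class SectionGrid:
    directions: np.ndarray  # (n, 3) unit vectors

    @property
    def n(self) -> int:
        return len(self.directions)

    @property
    def section_area_fraction(self) -> float:
        return 1.0 / self.n


def fibonacci_grid(n: int) -> SectionGrid:
    """n equal-area points on the unit sphere via the golden-angle lattice."""
    if n < 12:
        raise ValueError("a section grid needs at least 12 points")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    dirs = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return SectionGrid(directions=dirs)


def neighbor_candidates(structure: Structure, atom: Atom,
                        params: ContactParams | None = None,
                        radii: RadiusTable | None = None) -> list[Atom]:
    """Heavy atoms of other residues within the solvent-extended candidate cutoff.

    Two atoms are candidates for contact when their centers are closer than
    the sum of their van der Waals radii each enlarged by the probe radius
    (6.56 Å for a carbon–carbon pair with default radii).
    """
    params = params or ContactParams()
    radii = radii or RadiusTable()
    probe = params.probe_radius
    r_a = radii.get(atom.element) + probe
    out = []
    for b in structure.atoms:
        if not b.is_heavy or b.serial == atom.serial:
            continue
        if (b.chain, b.res_seq, b.icode) == (atom.chain, atom.res_seq, atom.icode):
            continue
        r_b = radii.get(b.element) + probe
        if np.linalg.norm(b.coords - atom.coords) <= r_a + r_b:
            out.append(b)
    return out


def assign_sections(center_a: np.ndarray, extended_radius_a: float,
                    neighbor_centers: np.ndarray, neighbor_extended_radii: np.ndarray,
                    neighbor_serials: np.ndarray, grid: SectionGrid) -> np.ndarray:
    """Owner (index into the neighbor arrays, or -1) for each grid section.

    A probe placed at center_a + R_a·u claims neighbors whose solvent-extended
    sphere it penetrates; among claimants the owner is the neighbor closest to
    center_a, with ties broken by lower atom serial.
    """
    owners = np.full(grid.n, -1, dtype=int)
    if len(neighbor_centers) == 0:
        return owners
    probes = center_a + extended_radius_a * grid.directions  # (n, 3)
    dist_to_a = np.linalg.norm(neighbor_centers - center_a, axis=1)
    order = np.lexsort((neighbor_serials, dist_to_a))  # closest first, serial tie-break
    unowned = np.ones(grid.n, dtype=bool)
    for j in order:
        if not unowned.any():
            break
        d = np.linalg.norm(probes[unowned] - neighbor_centers[j], axis=1)
        claimed = d <= neighbor_extended_radii[j]
        idx = np.flatnonzero(unowned)[claimed]
        owners[idx] = j
        unowned[idx] = False
    return owners


def _local_frame(center: np.ndarray, neighbor_centers: np.ndarray,
                 neighbor_serials: np.ndarray) -> np.ndarray:
    """Orthonormal frame (rows) anchored to the atom's neighborhood.

    The section lattice is expressed in this frame so that a rigid transform
    of all coordinates transforms the probe pattern with the molecule, making
    contact areas exactly invariant rather than invariant only up to lattice
    discreteness.  Axes: z toward the nearest neighbor, x toward the first
    non-collinear neighbor (deterministic serial tie-breaks); degenerate
    single-neighbor/collinear cases fall back to an arbitrary but fixed
    perpendicular.
    """
    offsets = neighbor_centers - center
    dists = np.linalg.norm(offsets, axis=1)
    order = np.lexsort((neighbor_serials, dists))
    u = offsets[order[0]] / dists[order[0]]
    v = None
    for j in order[1:]:
        w = offsets[j] - np.dot(offsets[j], u) * u
        norm = np.linalg.norm(w)
        if norm > 1e-6 * dists[j]:
            v = w / norm
            break
    if v is None:  # all neighbors collinear with u: any perpendicular works
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, u)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        v = np.cross(u, ref)
        v /= np.linalg.norm(v)
    return np.array([v, np.cross(u, v), u])


@dataclass
class ContactAreaMatrix:
    residues: list[Residue]
    areas: np.ndarray              # symmetric (n_res, n_res), Å²
    directed: np.ndarray           # directed (n_res, n_res): sections of row owned by col
    atom_detail: dict[tuple[int, int], float] = field(default_factory=dict)

    def pair_area(self, i: int, j: int) -> float:
        return float(self.areas[i, j])

    def to_records(self) -> list[dict]:
        rows = []
        n = len(self.residues)
        for i in range(n):
            for j in range(i + 1, n):
                if self.areas[i, j] > 0:
                    ri, rj = self.residues[i], self.residues[j]
                    rows.append({
                        "chain_i": ri.chain, "resseq_i": ri.res_seq, "resname_i": ri.res_name,
                        "chain_j": rj.chain, "resseq_j": rj.res_seq, "resname_j": rj.res_name,
                        "area": round(float(self.areas[i, j]), 3),
                    })
        return rows


def contact_areas(structure: Structure, selection: Sequence[Residue],
                  params: ContactParams | None = None,
                  radii: RadiusTable | None = None) -> ContactAreaMatrix:
    """Residue-against-residue contact-area matrix over `selection`.

    Every owned section of an atom in the selection contributes
    4π·R²/n_sections to the (residue, owner residue) cell, where R is the
    radius set by ``params.area_sphere``.  Occluding atoms outside the
    selection compete for sections (blocking them) but no area is accumulated
    toward them.  The symmetric matrix is the sum of the two directed totals.
    """
    params = params or ContactParams()
    radii = radii or RadiusTable()
    selection = list(selection)
    if not selection:
        raise ValueError("selection must contain at least one residue")
    grid = fibonacci_grid(params.n_sections)
    probe = params.probe_radius

    sel_index = {res.key: k for k, res in enumerate(selection)}

    if params.occluder_scope == "all-heavy-atoms":
        occluders = [a for a in structure.atoms if a.is_heavy]
    else:
        occluders = [a for res in selection for a in res.heavy_atoms()]
    occ_coords = np.array([a.coords for a in occluders], dtype=float)
    occ_radii = np.array([radii.get(a.element) + probe for a in occluders])
    occ_serials = np.array([a.serial for a in occluders])
    occ_reskey = [(a.chain, a.res_seq, a.icode) for a in occluders]
    tree = cKDTree(occ_coords)
    max_ext = float(occ_radii.max()) if len(occluders) else 0.0

    n = len(selection)
    directed = np.zeros((n, n))
    detail: dict[tuple[int, int], float] = {}

    for k, res in enumerate(selection):
        for atom in res.heavy_atoms():
            r_a = radii.get(atom.element) + probe
            cand = tree.query_ball_point(atom.coords, r_a + max_ext)
            cand = [j for j in cand
                    if occ_serials[j] != atom.serial
                    and occ_reskey[j] != res.key
                    and np.linalg.norm(occ_coords[j] - atom.coords) <= r_a + occ_radii[j]]
            if not cand:
                continue
            cand = np.array(cand)
            local_grid = SectionGrid(directions=grid.directions @ _local_frame(
                atom.coords, occ_coords[cand], occ_serials[cand]))
            owners = assign_sections(atom.coords, r_a, occ_coords[cand],
                                     occ_radii[cand], occ_serials[cand], local_grid)
            if params.area_sphere == "solvent-extended":
                r_area = r_a
            else:
                r_area = radii.get(atom.element)
            section_area = 4.0 * np.pi * r_area * r_area / grid.n
            owned = owners[owners >= 0]
            if owned.size == 0:
                continue
            counts = np.bincount(owned, minlength=len(cand))
            for local_j, cnt in enumerate(counts):
                if cnt == 0:
                    continue
                j = cand[local_j]
                key_b = occ_reskey[j]
                if key_b not in sel_index:
                    continue  # occluder blocks sections but accrues no area
                area = cnt * section_area
                directed[k, sel_index[key_b]] += area
                pair = (atom.serial, int(occ_serials[j]))
                detail[pair] = detail.get(pair, 0.0) + area

    symmetric = directed + directed.T
    np.fill_diagonal(symmetric, 0.0)
    return ContactAreaMatrix(residues=selection, areas=symmetric,
                             directed=directed, atom_detail=detail)
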