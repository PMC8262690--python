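"""Sidechain hydrogen-bond networks: fixed pH-7 protonation, Baker–Hubbard
geometric detection, and residue-level network partitioning.

Protonation uses fixed pH-7 charge states with deterministic geometric
hydrogen placement (no pKa estimation, no sidechain flipping): lysine and
arginine are charged, aspartate/glutamate carboxylates carry no proton,
histidine is neutral with the tautomer chosen to maximize nearby hydrogen-
bond partners.  An externally protonated structure (e.g. from a pKa-aware
pipeline) can be passed straight to :func:`detect_hbonds`, which keeps any
pre-existing hydrogens.

A hydrogen bond is a donor–H···acceptor triple with H···acceptor distance
d < 2.5 Å and donor–H–acceptor angle ϑ > 120°; donors are N–H and O–H
groups, acceptors are nitrogen and oxygen atoms.  Two residues belong to the
same network when a consecutive path of hydrogen bonds connects them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._graph import connected_components
from .structure_io import Atom, Residue, Structure, BACKBONE_ATOMS

logger = logging.getLogger(__name__)

__all__ = ["HBondParams", "HBond", "NetworkPartition", "protonate",
           "detect_hbonds", "build_networks", "find_networks"]

N_H_LENGTH = 1.01  # Å
O_H_LENGTH = 0.96  # Å
_TET = math.radians(109.5)


@dataclass
class HBondParams:
    theta_min: float = 120.0  # degrees, donor–H–acceptor angle must exceed this
    d_max: float = 2.5        # Å, H···acceptor distance must be below this
    scope: Literal["sidechain-only", "all"] = "sidechain-only"

    def __post_init__(self) -> None:
        if not 0 < self.theta_min < 180:
            raise ValueError("theta_min must be in (0, 180) degrees")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if self.scope not in ("sidechain-only", "all"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass
class HBond:
    donor: Atom
    hydrogen: Atom
    acceptor: Atom
    d: float       # H···acceptor distance, Å
    theta: float   # donor–H–acceptor angle, degrees

    def to_record(self, network_id: int | None = None) -> dict:
        rec = {
            "donor_residue": f"{self.donor.res_name}{self.donor.res_seq}:{self.donor.chain}",
            "donor_atom": self.donor.name,
            "hydrogen": self.hydrogen.name,
            "acceptor_residue": f"{self.acceptor.res_name}{self.acceptor.res_seq}:{self.acceptor.chain}",
            "acceptor_atom": self.acceptor.name,
            "distance": round(self.d, 3),
            "angle": round(self.theta, 1),
        }
        if network_id is not None:
            rec["network"] = network_id
        return rec


@dataclass
class NetworkPartition:
    networks: list[tuple[list[Residue], list[HBond]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self):
        return iter(self.networks)

    def __getitem__(self, i):
        return self.networks[i]

    def network_of(self, residue: Residue) -> int | None:
        for i, (members, _) in enumerate(self.networks):
            if residue.key in {m.key for m in members}:
                return i
        return None


# ---------------------------------------------------------------------------
# geometric hydrogen placement

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def _perp_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to `axis` and each other."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(axis, ref))
    e2 = np.cross(axis, e1)
    return e1, e2


def _cone_position(center: np.ndarray, parent: np.ndarray, bond_angle: float,
                   torsion: float, length: float,
                   torsion_ref: np.ndarray | None = None) -> np.ndarray:
    """Position at `length` from `center`, making `bond_angle` with the
    center→parent bond, at the given torsion about that bond.

    With `torsion_ref` (a grandparent atom), torsion 0 eclipses the reference
    and π is anti to it; otherwise torsion is measured in an arbitrary but
    deterministic frame.
    """
    u = _unit(parent - center)
    if torsion_ref is not None:
        w = torsion_ref - parent
        w_perp = w - np.dot(w, u) * u
        if np.linalg.norm(w_perp) > 1e-8:
            e1 = _unit(w_perp)
            e2 = np.cross(u, e1)
        else:
            e1, e2 = _perp_frame(u)
    else:
        e1, e2 = _perp_frame(u)
    direction = (math.cos(bond_angle) * u
                 + math.sin(bond_angle) * (math.cos(torsion) * e1 + math.sin(torsion) * e2))
    return center + length * _unit(direction)


def _trigonal_one(center: np.ndarray, n1: np.ndarray, n2: np.ndarray,
                  length: float) -> np.ndarray:
    """H completing a planar trigonal center with two heavy neighbors."""
    d = -(_unit(n1 - center) + _unit(n2 - center))
    return center + length * _unit(d)


def _trigonal_two(center: np.ndarray, parent: np.ndarray, plane_ref: np.ndarray,
                  length: float) -> list[np.ndarray]:
    """Two in-plane H on an sp² N bonded to one heavy atom (amide/guanidinium).

    The plane is defined by center, parent and `plane_ref` (an atom bonded to
    the parent); the two N→H directions are at 120° on either side of the
    N→parent bond.
    """
    u = _unit(parent - center)
    w = plane_ref - parent
    w_perp = w - np.dot(w, u) * u
    if np.linalg.norm(w_perp) < 1e-8:
        e1, _ = _perp_frame(u)
    else:
        e1 = _unit(w_perp)
    out = []
    for sign in (+1.0, -1.0):
        d = math.cos(math.radians(120.0)) * u + sign * math.sin(math.radians(120.0)) * e1
        out.append(center + length * _unit(d))
    return out


def _acceptor_atoms(structure: Structure, exclude_residue: Residue) -> list[Atom]:
    return [a for a in structure.atoms
            if a.element in ("N", "O")
            and (a.chain, a.res_seq, a.icode) != exclude_residue.key]


def _orient_hydroxyl(res: Residue, o_name: str, parent_name: str, grand_name: str,
                     structure: Structure, sp2: bool = False) -> np.ndarray | None:
    """Hydroxyl H: torsion scanned; pointed at the nearest acceptor within
    3.5 Å of the oxygen if one exists, else staggered (anti to grandparent)."""
    o, parent, grand = res.atom(o_name), res.atom(parent_name), res.atom(grand_name)
    if o is None or parent is None or grand is None:
        return None
    bond_angle = math.radians(111.0 if sp2 else 109.5)
    acceptors = [a for a in _acceptor_atoms(structure, res)
                 if np.linalg.norm(a.coords - o.coords) < 3.5]
    torsions = np.linspace(0.0, 2.0 * math.pi, 36, endpoint=False)
    candidates = [_cone_position(o.coords, parent.coords, bond_angle, t,
                                 O_H_LENGTH, torsion_ref=grand.coords)
                  for t in torsions]
    if acceptors:
        best = min(candidates,
                   key=lambda p: min(np.linalg.norm(p - a.coords) for a in acceptors))
        return best
    # staggered: anti to the grandparent heavy atom
    return _cone_position(o.coords, parent.coords, bond_angle, math.pi,
                          O_H_LENGTH, torsion_ref=grand.coords)


def _his_tautomer(res: Residue, structure: Structure) -> str:
    """Choose the neutral-His protonated nitrogen: the one with more potential
    hydrogen-bond partners (N/O of other residues) within 3.5 Å; tie → NE2."""
    counts = {}
    for n_name in ("ND1", "NE2"):
        atom = res.atom(n_name)
        if atom is None:
            continue
        counts[n_name] = sum(
            1 for a in _acceptor_atoms(structure, res)
            if np.linalg.norm(a.coords - atom.coords) < 3.5)
    if not counts:
        return "NE2"
    if counts.get("ND1", -1) > counts.get("NE2", -1):
        return "ND1"
    return "NE2"


def _sidechain_hydrogen_sites(res: Residue, structure: Structure) -> list[tuple[str, str, np.ndarray]]:
    """(H name, donor heavy-atom name, position) for the residue's fixed pH-7
    sidechain protons.  Residues with missing heavy atoms are skipped by the
    caller.  Asp/Glu carboxylates get no proton at pH 7."""
    sites: list[tuple[str, str, np.ndarray]] = []

    def atoms(*names):
        got = [res.atom(n) for n in names]
        if any(a is None for a in got):
            raise KeyError(f"{res.label} missing one of {names}")
        return [a.coords for a in got]

    name = res.res_name
    if name == "SER":
        pos = _orient_hydroxyl(res, "OG", "CB", "CA", structure)
        if pos is not None:
            sites.append(("HG", "OG", pos))
    elif name == "THR":
        pos = _orient_hydroxyl(res, "OG1", "CB", "CA", structure)
        if pos is not None:
            sites.append(("HG1", "OG1", pos))
    elif name == "TYR":
        pos = _orient_hydroxyl(res, "OH", "CZ", "CE1", structure, sp2=True)
        if pos is not None:
            sites.append(("HH", "OH", pos))
    elif name == "LYS":
        nz, ce, cd = atoms("NZ", "CE", "CD")
        for i, offset in enumerate((math.pi / 3, math.pi, 5 * math.pi / 3)):
            pos = _cone_position(nz, ce, _TET, offset, N_H_LENGTH, torsion_ref=cd)
            sites.append((f"HZ{i + 1}", "NZ", pos))
    elif name == "ARG":
        ne, cd, cz = atoms("NE", "CD", "CZ")
        sites.append(("HE", "NE", _trigonal_one(ne, cd, cz, N_H_LENGTH)))
        nh1, nh2 = atoms("NH1", "NH2")
        for n_name, n_pos, ref in (("NH1", nh1, nh2), ("NH2", nh2, nh1)):
            for i, pos in enumerate(_trigonal_two(n_pos, cz, ref, N_H_LENGTH)):
                sites.append((f"H{n_name[1:]}{i + 1}", n_name, pos))
    elif name == "ASN":
        nd2, cg, od1 = atoms("ND2", "CG", "OD1")
        for i, pos in enumerate(_trigonal_two(nd2, cg, od1, N_H_LENGTH)):
            sites.append((f"HD2{i + 1}", "ND2", pos))
    elif name == "GLN":
        ne2, cd, oe1 = atoms("NE2", "CD", "OE1")
        for i, pos in enumerate(_trigonal_two(ne2, cd, oe1, N_H_LENGTH)):
            sites.append((f"HE2{i + 1}", "NE2", pos))
    elif name == "TRP":
        ne1, cd1, ce2 = atoms("NE1", "CD1", "CE2")
        sites.append(("HE1", "NE1", _trigonal_one(ne1, cd1, ce2, N_H_LENGTH)))
    elif name in ("HIS", "HID", "HIE"):
        tautomer = {"HID": "ND1", "HIE": "NE2"}.get(name) or _his_tautomer(res, structure)
        if tautomer == "ND1":
            nd1, cg, ce1 = atoms("ND1", "CG", "CE1")
            sites.append(("HD1", "ND1", _trigonal_one(nd1, cg, ce1, N_H_LENGTH)))
        else:
            ne2, cd2, ce1 = atoms("NE2", "CD2", "CE1")
            sites.append(("HE2", "NE2", _trigonal_one(ne2, cd2, ce1, N_H_LENGTH)))
    return sites


def protonate(structure: Structure) -> Structure:
    """Return a copy with fixed pH-7 sidechain polar hydrogens placed.

    Hydrogens already present are kept unchanged and their donor atoms are
    not re-protonated.  Residues missing the required sidechain heavy atoms
    are skipped with a warning.
    """
    from .structure_io import _regroup  # shared residue regrouping

    new_atoms = [Atom(a.serial, a.name, a.element, a.res_name, a.res_seq,
                      a.icode, a.chain, a.coords.copy(), a.altloc)
                 for a in structure.atoms]
    next_serial = max((a.serial for a in new_atoms), default=0)
    additions: list[Atom] = []
    for res in structure.residues:
        existing_h_parents = set()
        for h in res.atoms:
            if h.element != "H":
                continue
            heavies = [(np.linalg.norm(h.coords - a.coords), a.name)
                       for a in res.atoms if a.is_heavy]
            if heavies and min(heavies)[0] < 1.3:
                existing_h_parents.add(min(heavies)[1])
        try:
            sites = _sidechain_hydrogen_sites(res, structure)
        except (KeyError, ValueError) as exc:
            logger.warning("skipping protonation of %s: %s", res.label, exc)
            continue
        for h_name, donor_name, pos in sites:
            if donor_name in existing_h_parents:
                continue
            next_serial += 1
            additions.append(Atom(next_serial, h_name, "H", res.res_name,
                                  res.res_seq, res.icode, res.chain, pos))

    # splice each residue's new hydrogens right after its heavy atoms
    by_res: dict[tuple, list[Atom]] = {}
    for h in additions:
        by_res.setdefault((h.chain, h.res_seq, h.icode, h.res_name), []).append(h)
    merged: list[Atom] = []
    for res in structure.residues:
        merged.extend(a for a in new_atoms if (a.chain, a.res_seq, a.icode, a.res_name)
                      == (res.chain, res.res_seq, res.icode, res.res_name))
        merged.extend(by_res.get((res.chain, res.res_seq, res.icode, res.res_name), []))
    for i, a in enumerate(merged, start=1):
        a.serial = i
    return _regroup(merged, structure.source_id)


# ---------------------------------------------------------------------------
# detection

def _donor_of(h: Atom, residue_atoms: list[Atom]) -> Atom | None:
    """The N/O the hydrogen is covalently attached to (nearest within 1.3 Å)."""
    best, best_d = None, 1.3
    for a in residue_atoms:
        if a.element not in ("N", "O"):
            continue
        d = float(np.linalg.norm(h.coords - a.coords))
        if d < best_d:
            best, best_d = a, d
    return best


def detect_hbonds(structure: Structure, params: HBondParams | None = None) -> list[HBond]:
    """All donor–H···acceptor triples meeting the geometric criterion.

    Requires a protonated structure (raises otherwise).  One bond is reported
    per (hydrogen, acceptor) pair; intra-residue pairs are excluded, and in
    the default sidechain-only scope both donor and acceptor atoms must be
    sidechain atoms.
    """
    params = params or HBondParams()
    hydrogens = [a for a in structure.atoms if a.element == "H"]
    if not hydrogens:
        raise ValueError("structure contains no hydrogens; run protonate() first "
                         "or supply an externally protonated file")
    res_atoms = {res.key: res.atoms for res in structure.residues}
    sidechain_only = params.scope == "sidechain-only"

    acceptors = [a for a in structure.atoms if a.element in ("N", "O")
                 and not (sidechain_only and a.name in BACKBONE_ATOMS)]
    acc_coords = np.array([a.coords for a in acceptors]) if acceptors else np.zeros((0, 3))

    bonds: list[HBond] = []
    for h in hydrogens:
        donor = _donor_of(h, res_atoms[(h.chain, h.res_seq, h.icode)])
        if donor is None:
            continue
        if sidechain_only and donor.name in BACKBONE_ATOMS:
            continue
        if len(acceptors) == 0:
            continue
        dists = np.linalg.norm(acc_coords - h.coords, axis=1)
        for idx in np.flatnonzero(dists < params.d_max):
            acc = acceptors[idx]
            if (acc.chain, acc.res_seq, acc.icode) == (donor.chain, donor.res_seq, donor.icode):
                continue
            v1 = donor.coords - h.coords
            v2 = acc.coords - h.coords
            cos_t = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            theta = math.degrees(math.acos(np.clip(cos_t, -1.0, 1.0)))
            if theta > params.theta_min:
                bonds.append(HBond(donor=donor, hydrogen=h, acceptor=acc,
                                   d=float(dists[idx]), theta=theta))
    return bonds


def build_networks(bonds: Sequence[HBond],
                   structure: Structure | None = None) -> NetworkPartition:
    """Partition residues into hydrogen-bond networks (graph components).

    A residue pair linked by several bonds contributes one edge.  Networks are
    ordered by descending size, then by first (chain, residue number).
    """
    res_by_key: dict[tuple, Residue] = {}
    if structure is not None:
        res_by_key = {res.key: res for res in structure.residues}

    def res_of(a: Atom) -> Residue:
        key = (a.chain, a.res_seq, a.icode)
        if key not in res_by_key:
            res_by_key[key] = Residue(a.chain, a.res_seq, a.icode, a.res_name, [a])
        return res_by_key[key]

    nodes: list[tuple] = []
    edges: list[tuple] = []
    for b in bonds:
        kd = (b.donor.chain, b.donor.res_seq, b.donor.icode)
        ka = (b.acceptor.chain, b.acceptor.res_seq, b.acceptor.icode)
        for k, atom in ((kd, b.donor), (ka, b.acceptor)):
            res_of(atom)
            if k not in nodes:
                nodes.append(k)
        edges.append((kd, ka))
    comps = connected_components(nodes, edges)
    networks = []
    for comp in comps:
        members = sorted((res_by_key[k] for k in comp),
                         key=lambda r: (r.chain, r.res_seq, r.icode))
        keys = set(comp)
        member_bonds = [b for b in bonds
                        if (b.donor.chain, b.donor.res_seq, b.donor.icode) in keys]
        networks.append((members, member_bonds))
    networks.sort(key=lambda nw: (-len(nw[0]),
                                  (nw[0][0].chain, nw[0][0].res_seq, nw[0][0].icode)))
    return NetworkPartition(networks)


def find_networks(structure: Structure, params: HBondParams | None = None
                  ) -> tuple[NetworkPartition, list[HBond], Structure]:
    """End-to-end: protonate (if needed), detect bonds, build networks."""
    if not any(a.element == "H" for a in structure.atoms):
        structure = protonate(structure)
    bonds = detect_hbonds(structure, params)
    return build_networks(bonds, structure), bonds, structure
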