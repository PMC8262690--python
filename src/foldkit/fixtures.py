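"""Synthetic PDB fixtures with exactly controlled geometry.

Residue pairs at set separations, ideal donor–H–acceptor triples and
degenerate records (altlocs, extra models, HETATM waters) are generated
programmatically so that every analysis is testable without downloading any
structure.  Idealized residue geometry comes from the chemical component
dictionary bundled with biotite; fixtures are geometric unit-test scaffolds,
not realistic protein decoys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from biotite.structure.info import residue as _ccd_residue
from scipy.optimize import brentq
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure_io import _format_pdb_atom

__all__ = ["FixtureSpec", "residue_template", "make_pair", "make_chain",
           "make_decorated", "make_hbond_triple"]

SUPPORTED = {"ALA", "ARG", "ASN", "ASP", "GLN", "GLU", "GLY", "HIS", "ILE",
             "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"}


@dataclass
class FixtureSpec:
    residues: list[str]
    separations: list[float] = field(default_factory=list)
    decorations: tuple[str, ...] = ()
    seed: int = 0


def residue_template(res_name: str, include_hydrogens: bool = False
                     ) -> tuple[list[str], list[str], np.ndarray]:
    """(atom names, elements, coordinates) of an idealized residue.

    The terminal OXT/HXT of the component definition is dropped so templates
    look like mid-chain residues.
    """
    res_name = res_name.upper()
    if res_name not in SUPPORTED:
        raise ValueError(f"unsupported residue type {res_name!r}")
    arr = _ccd_residue(res_name)
    keep = (arr.atom_name != "OXT") & (arr.atom_name != "HXT") & (arr.atom_name != "H2")
    if not include_hydrogens:
        keep &= arr.element != "H"
    names = list(arr.atom_name[keep])
    elements = [e.upper() for e in arr.element[keep]]
    coords = np.array(arr.coord[keep], dtype=float)
    return names, elements, coords


def _orient(coords: np.ndarray, names: list[str], contact_atom: str,
            direction: np.ndarray) -> np.ndarray:
    """Center on CA and rotate so the CA→contact-atom vector points along
    `direction` (makes the contact atom the face of the residue)."""
    ca = coords[names.index("CA")]
    coords = coords - ca
    v = coords[names.index(contact_atom)]
    if np.linalg.norm(v) < 1e-8:
        return coords
    rot, _ = Rotation.align_vectors([direction], [v / np.linalg.norm(v)])
    return coords @ rot.as_matrix().T


def _default_contact_atom(names: list[str]) -> str:
    """Last sidechain heavy atom (farthest out along the chain) or CA."""
    sidechain = [n for n in names if n not in ("N", "CA", "C", "O")]
    return sidechain[-1] if sidechain else "CA"


def make_pair(restype_a: str, restype_b: str, separation: float,
              contact_atom_a: str | None = None, contact_atom_b: str | None = None,
              chain: str = "A", include_hydrogens: bool = False) -> str:
    """PDB text with two idealized residues whose closest heavy atoms are
    exactly `separation` Å apart.

    With explicit contact atoms the residues are oriented so those atoms face
    each other and realize the minimum distance.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    names_a, elem_a, xyz_a = residue_template(restype_a, include_hydrogens)
    names_b, elem_b, xyz_b = residue_template(restype_b, include_hydrogens)
    contact_atom_a = contact_atom_a or _default_contact_atom(names_a)
    contact_atom_b = contact_atom_b or _default_contact_atom(names_b)
    xyz_a = _orient(xyz_a, names_a, contact_atom_a, np.array([1.0, 0.0, 0.0]))
    xyz_b = _orient(xyz_b, names_b, contact_atom_b, np.array([-1.0, 0.0, 0.0]))

    heavy_a = np.array([e != "H" for e in elem_a])
    heavy_b = np.array([e != "H" for e in elem_b])

    def min_dist(t: float) -> float:
        return float(cdist(xyz_a[heavy_a], xyz_b[heavy_b] + np.array([t, 0.0, 0.0])).min())

    # translate B along +x so the global heavy-atom minimum equals `separation`
    lo = 0.0
    hi = 10.0 * (separation + 10.0)
    while min_dist(lo) > separation:  # templates may already be far apart
        lo -= 5.0
        if lo < -100:
            raise RuntimeError("could not bracket the requested separation")
    t = brentq(lambda t: min_dist(t) - separation, lo, hi, xtol=1e-10)
    xyz_b = xyz_b + np.array([t, 0.0, 0.0])

    lines = []
    serial = 0
    for res_seq, (names, elems, xyz, res_name) in enumerate(
            [(names_a, elem_a, xyz_a, restype_a.upper()),
             (names_b, elem_b, xyz_b, restype_b.upper())], start=1):
        for name, el, pos in zip(names, elems, xyz):
            serial += 1
            lines.append(_format_pdb_atom(serial, name, res_name, chain, res_seq, pos, el))
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_chain(restypes: Sequence[str], spacing: float = 6.0, chain: str = "A",
               axis: np.ndarray | None = None, jitter: float = 0.0,
               seed: int = 0) -> str:
    """PDB text with idealized residues placed along an axis, `spacing` Å
    between consecutive CA atoms (optionally jittered, seeded)."""
    axis = np.array([1.0, 0.0, 0.0]) if axis is None else np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    rng = np.random.default_rng(seed)
    lines = []
    serial = 0
    for res_seq, res_name in enumerate(restypes, start=1):
        names, elems, xyz = residue_template(res_name)
        ca = xyz[names.index("CA")]
        offset = (res_seq - 1) * spacing * axis - ca
        if jitter > 0:
            offset = offset + rng.normal(scale=jitter, size=3)
        for name, el, pos in zip(names, elems, xyz + offset):
            serial += 1
            lines.append(_format_pdb_atom(serial, name, res_name.upper(), chain,
                                          res_seq, pos, el))
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_hbond_triple(d: float = 2.0, theta: float = 180.0) -> str:
    """Two-serine PDB text with an explicit O–H···O geometry.

    Residue 1 carries a hydroxyl hydrogen (HG) placed so that the H···OG2
    distance is `d` and the OG1–H–OG2 angle is `theta` degrees; residue 2 is
    the acceptor.  Used to probe the detection cutoffs exactly.
    """
    names, elems, xyz = residue_template("SER")
    og = names.index("OG")
    # residue 1 at origin with OG on +x
    xyz_a = _orient(xyz, names, "OG", np.array([1.0, 0.0, 0.0]))
    og_a = xyz_a[og]
    h_pos = og_a + np.array([0.96, 0.0, 0.0])
    # acceptor O at distance d from H, at angle theta to the O–H bond
    ang = math.radians(180.0 - theta)
    acc_dir = np.array([math.cos(ang), math.sin(ang), 0.0])
    acc_pos = h_pos + d * acc_dir
    # build residue 2 so its OG sits at acc_pos, pointing back at H
    xyz_b = _orient(xyz, names, "OG", np.array([-1.0, 0.0, 0.0]))
    xyz_b = xyz_b + (acc_pos - xyz_b[og])

    lines = []
    serial = 0
    for name, el, pos in zip(names, elems, xyz_a):
        serial += 1
        lines.append(_format_pdb_atom(serial, name, "SER", "A", 1, pos, el))
    serial += 1
    lines.append(_format_pdb_atom(serial, "HG", "SER", "A", 1, h_pos, "H"))
    for name, el, pos in zip(names, elems, xyz_b):
        serial += 1
        lines.append(_format_pdb_atom(serial, name, "SER", "A", 2, pos, el))
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_decorated(base: str, decorations: Iterable[str]) -> str:
    """Add degenerate records to fixture PDB text for parser tests.

    Decorations: ``altloc`` duplicates the first sidechain atom as states A
    (occupancy 0.6) and B (occupancy 0.4, shifted 0.5 Å); ``multimodel``
    wraps the coordinates as MODEL 1 and adds a shifted MODEL 2; ``hetatm``
    appends a HETATM water.
    """
    decorations = set(decorations)
    unknown = decorations - {"altloc", "multimodel", "hetatm"}
    if unknown:
        raise ValueError(f"unknown decorations: {sorted(unknown)}")
    lines = [ln for ln in base.splitlines() if ln.startswith("ATOM")]

    if "altloc" in decorations:
        out = []
        done = False
        for ln in lines:
            name = ln[12:16].strip()
            if not done and name not in ("N", "CA", "C", "O"):
                a_state = ln[:16] + "A" + ln[17:54] + f"{0.60:6.2f}" + ln[60:]
                x = float(ln[30:38]) + 0.5
                b_state = (ln[:16] + "B" + ln[17:30] + f"{x:8.3f}" + ln[38:54]
                           + f"{0.40:6.2f}" + ln[60:])
                out.extend([a_state, b_state])
                done = True
            else:
                out.append(ln)
        lines = out

    if "hetatm" in decorations:
        serial = len(lines) + 1
        lines.append(_format_pdb_atom(serial, "O", "HOH", "A", 901,
                                      (50.0, 50.0, 50.0), "O", het=True))

    if "multimodel" in decorations:
        shifted = []
        for ln in lines:
            x = float(ln[30:38]) + 25.0
            shifted.append(ln[:30] + f"{x:8.3f}" + ln[38:])
        lines = (["MODEL        1"] + lines + ["ENDMDL", "MODEL        2"]
                 + shifted + ["ENDMDL"])

    return "\n".join(lines + ["END"]) + "\n"
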