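"""Read PDB structures into a normalized atom table; radii, CSV and PyMOL-script output.

Normalization rules: only the first MODEL of a multi-model (e.g. NMR) file is
used; for alternate conformations only the first state of each atom is kept;
waters and (by default) other HETATM ligands are excluded; selenomethionine
(MSE) is treated as methionine.  Residue numbering and insertion codes are
taken verbatim from the file.
"""

from __future__ import annotations

import csv
import io
import logging
import math
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "RadiusTable",
    "ParseError",
    "parse_structure",
    "read_structure",
    "fetch_pdb",
    "write_table",
    "write_viewer_script",
    "write_pdb",
    "THREE_TO_ONE",
]

#: Backbone atom names (everything else in a standard residue is sidechain).
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


class ParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    icode: str
    chain: str
    coords: np.ndarray
    altloc: str = ""

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS or (
            self.element == "H" and self.name in {"H", "H1", "H2", "H3", "HA", "HXT"}
        )

    def __repr__(self) -> str:  # compact; full repr is noisy in test output
        return (f"Atom({self.serial} {self.name} {self.res_name}"
                f"{self.res_seq}{self.icode.strip()}/{self.chain})")


@dataclass
class Residue:
    chain: str
    res_seq: int
    icode: str
    res_name: str
    atoms: list[Atom]
    index: int = 0

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_seq, self.icode)

    @property
    def label(self) -> str:
        return f"{self.res_name}{self.res_seq}{self.icode.strip()}:{self.chain}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def __repr__(self) -> str:
        return f"Residue({self.label})"


@dataclass
class Structure:
    atoms: list[Atom]
    residues: list[Residue]
    source_id: str = ""

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        sel = [a for a in self.atoms if a.is_heavy] if heavy_only else self.atoms
        return np.array([a.coords for a in sel], dtype=float)

    def chain_sequence(self, chain: str | None = None) -> str:
        """One-letter sequence of the parsed residues in file order."""
        letters = []
        for res in self.residues:
            if chain is not None and res.chain != chain:
                continue
            letters.append(THREE_TO_ONE.get(res.res_name, "X"))
        return "".join(letters)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigid-transformed copy (used for invariance checks)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        new_atoms = []
        for a in self.atoms:
            new_atoms.append(Atom(a.serial, a.name, a.element, a.res_name,
                                  a.res_seq, a.icode, a.chain,
                                  rotation @ a.coords + translation, a.altloc))
        return _regroup(new_atoms, self.source_id)

    def __repr__(self) -> str:
        return (f"Structure({self.source_id or 'unnamed'}: "
                f"{len(self.residues)} residues, {len(self.atoms)} atoms)")


@dataclass
class RadiusTable:
    """Van der Waals radii (Å) per element plus the water probe radius.

    The carbon radius of 1.88 Å together with the 1.4 Å probe gives the
    6.56 Å carbon–carbon candidate cutoff used in the contact algorithm:
    2 × (1.88 + 1.4) = 6.56.
    """

    radii: dict[str, float] = field(default_factory=lambda: {
        "C": 1.88, "N": 1.64, "O": 1.42, "S": 1.77, "H": 1.0, "SE": 1.9,
    })
    probe_radius: float = 1.4
    default_radius: float = 1.8

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("all van der Waals radii must be positive")

    def get(self, element: str) -> float:
        el = element.upper()
        if el in self.radii:
            return self.radii[el]
        logger.warning("no van der Waals radius for element %r; using default %.2f Å",
                       element, self.default_radius)
        return self.default_radius


def vdw_radius(element: str, table: RadiusTable | None = None) -> float:
    """Van der Waals radius of `element` in Å (falls back to the table default)."""
    return (table or RadiusTable()).get(element)


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {atom_name!r}")
    if stripped[:2].upper() in ("SE", "CL", "BR", "FE", "ZN", "MG", "NA", "MN"):
        return stripped[:2].upper()
    return stripped[0].upper()


def _regroup(atoms: list[Atom], source_id: str) -> Structure:
    residues: list[Residue] = []
    seen: dict[tuple[str, int, str, str], Residue] = {}
    for a in atoms:
        key = (a.chain, a.res_seq, a.icode, a.res_name)
        if key not in seen:
            res = Residue(a.chain, a.res_seq, a.icode, a.res_name, [], index=len(residues))
            seen[key] = res
            residues.append(res)
        seen[key].atoms.append(a)
    return Structure(atoms=atoms, residues=residues, source_id=source_id)


def parse_structure(pdb_text: str, model_policy: str = "first",
                    include_hetero: bool = False, source_id: str = "") -> Structure:
    """Parse PDB text into a normalized :class:`Structure`.

    Only the first model is kept (`model_policy="first"`, the only policy);
    for altloc groups the first state wins; waters are always excluded;
    non-water HETATM ligands are excluded unless `include_hetero`; MSE is
    converted to MET.  Hydrogens present in the file are retained.
    """
    if model_policy != "first":
        raise ValueError(f"unsupported model_policy {model_policy!r}")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"malformed PDB input: {exc}") from exc
    if len(st) == 0:
        raise ParseError("no ATOM records found")

    model = st[0]
    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            res_name = res.name
            if het:
                if res.is_water():
                    continue
                if res_name == "MSE":
                    res_name = "MET"
                elif not include_hetero:
                    logger.info("excluding HETATM residue %s %s%d", res.name,
                                chain.name, res.seqid.num)
                    continue
            seen_names: set[str] = set()
            for at in res:
                if at.name in seen_names:  # later altloc state of the same atom
                    continue
                seen_names.add(at.name)
                name = at.name
                element = "H" if at.element.is_hydrogen else at.element.name.upper()
                if element in ("", "X"):
                    element = _infer_element(name)
                if res.name == "MSE" and name == "SE":
                    name, element = "SD", "S"
                pos = np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float)
                if not np.all(np.isfinite(pos)):
                    raise ParseError(f"non-finite coordinates for atom {at.name} "
                                     f"in residue {chain.name}/{res.seqid.num}")
                serial += 1
                atoms.append(Atom(
                    serial=serial, name=name, element=element, res_name=res_name,
                    res_seq=res.seqid.num, icode=(res.seqid.icode or " ").strip() or " ",
                    chain=chain.name, coords=pos,
                    altloc=(at.altloc or "").replace("\x00", "").strip(),
                ))
    if not atoms:
        raise ParseError("no ATOM records found")
    return _regroup(atoms, source_id or (st.name or "").lower())


def read_structure(path: str | Path, **kwargs) -> Structure:
    path = Path(path)
    return parse_structure(path.read_text(), source_id=kwargs.pop("source_id", path.stem),
                           **kwargs)


def fetch_pdb(pdb_id: str, dest: str | Path, timeout: float = 30.0) -> Path:
    """Download an entry from the PDB (requires network access)."""
    pdb_id = pdb_id.lower()
    if len(pdb_id) != 4 or not pdb_id.isalnum():
        raise ValueError(f"not a 4-character PDB identifier: {pdb_id!r}")
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        dest.write_bytes(resp.read())
    return dest


# ---------------------------------------------------------------------------
# output helpers

def write_table(rows: Sequence[Mapping], destination: str | Path,
                fieldnames: Sequence[str] | None = None) -> Path:
    """Write records to an RFC-4180 CSV file (header row first, CRLF, UTF-8)."""
    destination = Path(destination)
    if fieldnames is None:
        if not rows:
            raise ValueError("fieldnames required when rows is empty")
        fieldnames = list(rows[0].keys())
    with destination.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(fieldnames))
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
    return destination


#: Deterministic color cycle for viewer scripts (one distinct color per group).
PALETTE = ["red", "green", "yellow", "orange", "blue", "magenta", "cyan",
           "salmon", "limegreen", "slate", "hotpink", "teal", "wheat", "purple"]


def write_viewer_script(structure_label: str, groups: Sequence[tuple[str, Sequence[Residue]]],
                        destination: str | Path, structure: Structure | None = None) -> Path:
    """Write a PyMOL .pml script: load the structure, one colored selection per group.

    `groups` is a sequence of (name, residues) pairs; colors are assigned from
    a fixed palette in order.  If `structure` is given, group members are
    validated against it.
    """
    destination = Path(destination)
    if structure is not None:
        known = {res.key for res in structure.residues}
        missing = [res.label for _, residues in groups
                   for res in residues if res.key not in known]
        if missing:
            raise ValueError(f"residues not present in structure: {', '.join(missing)}")
    lines = [f"load {structure_label}"]
    for i, (name, residues) in enumerate(groups):
        by_chain: dict[str, list[str]] = {}
        for res in residues:
            by_chain.setdefault(res.chain, []).append(f"{res.res_seq}{res.icode.strip()}")
        clauses = [f"(chain {ch} and resi {'+'.join(nums)})"
                   for ch, nums in sorted(by_chain.items())]
        lines.append(f"select {name}, {' or '.join(clauses)}")
        lines.append(f"color {PALETTE[i % len(PALETTE)]}, {name}")
    destination.write_text("\n".join(lines) + "\n")
    return destination


def _format_pdb_atom(serial: int, name: str, res_name: str, chain: str, res_seq: int,
                     coords: Iterable[float], element: str, altloc: str = " ",
                     icode: str = " ", occupancy: float = 1.0, het: bool = False) -> str:
    record = "HETATM" if het else "ATOM  "
    # names of <4 chars for 1-letter elements start in column 14
    if len(name) < 4 and len(element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    x, y, z = coords
    return (f"{record}{serial:>5d} {name_field}{altloc:1s}{res_name:>3s} {chain:1s}"
            f"{res_seq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}"
            f"{0.0:6.2f}          {element:>2s}")


def write_pdb(structure: Structure, destination: str | Path | None = None) -> str:
    """Serialize a Structure back to PDB text (one model, normalized atoms)."""
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        lines.append(_format_pdb_atom(i, a.name, a.res_name, a.chain, a.res_seq,
                                      a.coords, a.element,
                                      altloc=a.altloc or " ", icode=a.icode or " "))
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if destination is not None:
        Path(destination).write_text(text)
    return text
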