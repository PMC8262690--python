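"""Salt-bridge detection and networks.

A salt bridge is an acidic sidechain oxygen (Asp OD1/OD2, Glu OE1/OE2)
within 4 Å (strictly below) of a basic sidechain nitrogen (Lys NZ, Arg
NE/NH1/NH2).  Histidine is neutral at pH 7 and excluded by default; chain
termini can optionally contribute their charged groups.  Networks are the
connected components of the residue graph induced by the bridges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from ._graph import connected_components
from .structure_io import Atom, Residue, Structure

__all__ = ["SaltBridgeParams", "SaltBridge", "SaltBridgeNetwork",
           "detect_salt_bridges", "bridge_networks", "find_salt_bridges"]

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
HIS_ATOMS = ("ND1", "NE2")


@dataclass
class SaltBridgeParams:
    cutoff: float = 4.0          # Å, strict less-than
    include_his: bool = False    # add HIS ND1/NE2 as basic nitrogens
    include_termini: bool = False  # add OXT (acidic) and N-terminal N (basic)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class SaltBridge:
    acidic: Atom
    basic: Atom
    distance: float

    def to_record(self, network_id: int | None = None) -> dict:
        rec = {
            "acidic_residue": f"{self.acidic.res_name}{self.acidic.res_seq}:{self.acidic.chain}",
            "acidic_atom": self.acidic.name,
            "basic_residue": f"{self.basic.res_name}{self.basic.res_seq}:{self.basic.chain}",
            "basic_atom": self.basic.name,
            "distance": round(self.distance, 3),
        }
        if network_id is not None:
            rec["network"] = network_id
        return rec


@dataclass
class SaltBridgeNetwork:
    residues: list[Residue]
    bridges: list[SaltBridge] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.residues)


def _charged_atoms(structure: Structure, params: SaltBridgeParams) -> tuple[list[Atom], list[Atom]]:
    acidic, basic = [], []
    first_res_per_chain = {}
    for res in structure.residues:
        first_res_per_chain.setdefault(res.chain, res.key)
    for res in structure.residues:
        for name in ACIDIC_ATOMS.get(res.res_name, ()):
            a = res.atom(name)
            if a is not None:
                acidic.append(a)
        for name in BASIC_ATOMS.get(res.res_name, ()):
            a = res.atom(name)
            if a is not None:
                basic.append(a)
        if params.include_his and res.res_name == "HIS":
            for name in HIS_ATOMS:
                a = res.atom(name)
                if a is not None:
                    basic.append(a)
        if params.include_termini:
            oxt = res.atom("OXT")
            if oxt is not None:
                acidic.append(oxt)
            if res.key == first_res_per_chain[res.chain]:
                n = res.atom("N")
                if n is not None:
                    basic.append(n)
    return acidic, basic


def detect_salt_bridges(structure: Structure,
                        params: SaltBridgeParams | None = None) -> list[SaltBridge]:
    """All acidic-O/basic-N atom pairs with distance strictly below the cutoff."""
    params = params or SaltBridgeParams()
    acidic, basic = _charged_atoms(structure, params)
    if not acidic or not basic:
        return []
    d = cdist(np.array([a.coords for a in acidic]),
              np.array([b.coords for b in basic]))
    bridges = []
    for i, j in zip(*np.nonzero(d < params.cutoff)):
        a, b = acidic[i], basic[j]
        if (a.chain, a.res_seq, a.icode) == (b.chain, b.res_seq, b.icode):
            continue  # a residue cannot bridge to itself (termini options)
        bridges.append(SaltBridge(acidic=a, basic=b, distance=float(d[i, j])))
    bridges.sort(key=lambda br: (br.acidic.serial, br.basic.serial))
    return bridges


def bridge_networks(bridges: Sequence[SaltBridge],
                    structure: Structure | None = None) -> list[SaltBridgeNetwork]:
    """Connected components over residues; residue pairs with several atom
    pairs below the cutoff count as one edge.  Ordered by descending size,
    then residue number."""
    res_by_key: dict[tuple, Residue] = {}
    if structure is not None:
        res_by_key = {res.key: res for res in structure.residues}

    def key_of(a: Atom) -> tuple:
        k = (a.chain, a.res_seq, a.icode)
        if k not in res_by_key:
            res_by_key[k] = Residue(a.chain, a.res_seq, a.icode, a.res_name, [a])
        return k

    nodes: list[tuple] = []
    edges = []
    for br in bridges:
        ka, kb = key_of(br.acidic), key_of(br.basic)
        for k in (ka, kb):
            if k not in nodes:
                nodes.append(k)
        edges.append((ka, kb))
    comps = connected_components(nodes, edges)
    networks = []
    for comp in comps:
        keys = set(comp)
        members = sorted((res_by_key[k] for k in comp),
                         key=lambda r: (r.chain, r.res_seq, r.icode))
        member_bridges = [br for br in bridges
                          if (br.acidic.chain, br.acidic.res_seq, br.acidic.icode) in keys]
        networks.append(SaltBridgeNetwork(residues=members, bridges=member_bridges))
    networks.sort(key=lambda nw: (-nw.size,
                                  (nw.residues[0].chain, nw.residues[0].res_seq)))
    return networks


def find_salt_bridges(structure: Structure, params: SaltBridgeParams | None = None
                      ) -> tuple[list[SaltBridgeNetwork], list[SaltBridge]]:
    """End-to-end: detect bridges and group them into networks."""
    bridges = detect_salt_bridges(structure, params)
    return bridge_networks(bridges, structure), bridges
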