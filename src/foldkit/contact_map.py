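"""Residue contact maps: minimum inter-atomic distance between residue pairs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_io import Residue, Structure

__all__ = ["DistanceMatrix", "contact_matrix"]


@dataclass
class DistanceMatrix:
    residues: list[Residue]
    distances: np.ndarray  # symmetric (n, n), Å, zero diagonal

    @property
    def labels(self) -> list[str]:
        return [res.label for res in self.residues]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.labels, columns=self.labels)

    def to_long_records(self) -> list[dict]:
        rows = []
        n = len(self.residues)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({"res_i": self.labels[i], "res_j": self.labels[j],
                             "distance": round(float(self.distances[i, j]), 3)})
        return rows

    def thresholded(self, cutoff: float) -> np.ndarray:
        """Binary contact matrix (1 where distance ≤ cutoff, diagonal 0)."""
        contacts = (self.distances <= cutoff).astype(int)
        np.fill_diagonal(contacts, 0)
        return contacts


def contact_matrix(structure: Structure, include_hydrogens: bool = False,
                   chain: str | None = None) -> DistanceMatrix:
    """All-against-all residue distance matrix.

    Entry (i, j) is the minimum distance between any atom of residue i and
    any atom of residue j (heavy atoms only by default); the diagonal is 0.
    """
    residues = [res for res in structure.residues
                if chain is None or res.chain == chain]
    if not residues:
        raise ValueError("structure contains no residues (after chain filter)")
    atom_lists = []
    for res in residues:
        atoms = res.atoms if include_hydrogens else res.heavy_atoms()
        atom_lists.append(np.array([a.coords for a in atoms], dtype=float))
    coords = np.concatenate(atom_lists)
    counts = [len(a) for a in atom_lists]
    starts = np.concatenate([[0], np.cumsum(counts)])
    d_atoms = cdist(coords, coords)
    n = len(residues)
    out = np.zeros((n, n))
    for i in range(n):
        bi = slice(starts[i], starts[i + 1])
        for j in range(i + 1, n):
            bj = slice(starts[j], starts[j + 1])
            out[i, j] = out[j, i] = d_atoms[bi, bj].min()
    return DistanceMatrix(residues=residues, distances=out)
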