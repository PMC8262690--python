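"""Connected components over small residue graphs (scipy csgraph backend)."""

from __future__ import annotations

from typing import Hashable, Iterable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc


def connected_components(nodes: Sequence[Hashable],
                         edges: Iterable[tuple[Hashable, Hashable]]) -> list[list]:
    """Partition `nodes` into connected components of the undirected edge list.

    Components preserve the input node order internally; the returned list is
    ordered by first node appearance (callers re-sort as needed).
    """
    nodes = list(nodes)
    if not nodes:
        return []
    index = {node: i for i, node in enumerate(nodes)}
    rows, cols = [], []
    for a, b in edges:
        rows.append(index[a])
        cols.append(index[b])
    n = len(nodes)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = _cc(adj, directed=False)
    comps: list[list] = [[] for _ in range(n_comp)]
    for node, lab in zip(nodes, labels):
        comps[lab].append(node)
    comps.sort(key=lambda c: index[c[0]])
    return comps
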