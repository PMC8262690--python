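"""Detect ILV hydrophobic clusters in a small synthetic protein.

Builds a ten-residue chain with a loose hydrophobic patch, computes
section-based atomic contact areas over the Ile/Leu/Val residues and groups
them into clusters.
"""

from foldkit import find_clusters, parse_structure
from foldkit.fixtures import make_chain
from foldkit.hydrophobic_clusters import cluster_summary

structure = parse_structure(make_chain(
    ["LEU", "VAL", "ILE", "LEU", "SER", "GLU", "LYS", "VAL"],
    spacing=5.5, seed=4))

clusters, matrix = find_clusters(structure)

print(f"{len(structure.residues)} residues, "
      f"{sum(r.res_name in {'ILE', 'LEU', 'VAL'} for r in structure.residues)} ILV, "
      f"{len(clusters)} cluster(s)")
for i, cluster in enumerate(clusters):
    s = cluster_summary(cluster)
    print(f"cluster {i}: {s['size']} residues [{s['residues']}]")
    print(f"  total contact area {s['total_area']} A^2 over {s['n_contacts']} "
          f"contact(s); per contact {s['area_per_contact']} A^2")

# The total area sums each contacting residue pair's overlap once; residues
# join a cluster when a pairwise path of >=10 A^2 contacts connects them.
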