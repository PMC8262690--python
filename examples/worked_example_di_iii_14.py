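"""Full analysis of the designed IF3-like protein Di-III_14 (PDB 2LN3).

Requires network access once to fetch the entry (or a cached copy at
data/2ln3.pdb).  Reports the hydrophobic cluster, hydrogen-bond networks,
salt-bridge networks and the κ/FCR charge metrics of the chain.
"""

from pathlib import Path

from foldkit import (ChargePattern, fetch_pdb, find_clusters, find_networks,
                     find_salt_bridges, read_structure)
from foldkit.hydrophobic_clusters import cluster_summary

path = Path(__file__).resolve().parent.parent / "data" / "2ln3.pdb"
if not path.exists():
    print("fetching 2LN3 from the PDB ...")
    fetch_pdb("2ln3", path)
structure = read_structure(path)

clusters, _ = find_clusters(structure)
print(f"hydrophobic clusters: {len(clusters)}")
for i, c in enumerate(clusters):
    s = cluster_summary(c)
    print(f"  cluster {i}: {s['size']} residues, {s['total_area']} A^2, "
          f"{s['n_contacts']} contacts, {s['area_per_contact']} A^2 per contact")

partition, bonds, _ = find_networks(structure)
print(f"hydrogen-bond networks: {len(partition)} ({len(bonds)} bonds)")
members, _ = partition[0]
print(f"  largest: {[r.label for r in members]}")

networks, bridges = find_salt_bridges(structure)
print(f"salt-bridge networks: {len(networks)} ({len(bridges)} atom pairs)")

pattern = ChargePattern.from_sequence(structure.chain_sequence())
print(f"FCR = {pattern.fcr:.2f}, kappa = {pattern.kappa:.2f}")
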