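"""Find sidechain hydrogen-bond networks in a constructed serine/aspartate pair.

The fixture places the serine hydroxyl oxygen 2.8 Å from an aspartate
carboxylate oxygen; after fixed pH-7 protonation the hydroxyl proton points
at the acceptor, yielding one hydrogen bond and one two-residue network.
"""

from foldkit import find_networks, parse_structure
from foldkit.fixtures import make_pair

structure = parse_structure(make_pair("SER", "ASP", 2.8,
                                      contact_atom_a="OG", contact_atom_b="OD1"))
partition, bonds, protonated = find_networks(structure)

print(f"{sum(a.element == 'H' for a in protonated.atoms)} hydrogen(s) placed")
for b in bonds:
    print(f"bond: {b.donor.res_name}{b.donor.res_seq} {b.donor.name}-{b.hydrogen.name}"
          f" ... {b.acceptor.name} {b.acceptor.res_name}{b.acceptor.res_seq}"
          f"  d = {b.d:.2f} A, theta = {b.theta:.0f} deg")
print(f"{len(partition)} network(s)")
for i, (members, member_bonds) in enumerate(partition):
    print(f"network {i}: {[r.label for r in members]} ({len(member_bonds)} bond(s))")

# d is the hydrogen-to-acceptor distance (must be < 2.5 A) and theta the
# donor-H-acceptor angle (must exceed 120 deg); residues joined by a path of
# such bonds share a network.
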