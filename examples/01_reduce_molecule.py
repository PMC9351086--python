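"""Reduce a molecule to its pharmacophore graph.

Builds acetaminophen from SMILES, collapses it into pharmacophore nodes and
prints the node types, member atoms and weighted edges.  The two-letter
symbols name (ring category, feature category) pairs — e.g. Sc = aromatic
ring with no feature, Ga = acyclic joint donor/acceptor.
"""

from pharmgnn import parse_molecule, reduce_graph

graph = parse_molecule("CC(=O)Nc1ccc(O)cc1")  # acetaminophen
rg = reduce_graph(graph)

print(f"molecule: {graph.canonical_smiles}  ({graph.n_atoms} heavy atoms)")
print(f"reduced graph: {rg.n_nodes} pharmacophore nodes")
for i, node in enumerate(rg.nodes):
    t = node.type
    print(f"  node {i}: {t.symbol:3s} {t.ring.name.lower():15s} "
          f"{t.feature.name.lower():20s} atoms {sorted(node.member_atoms)}")
for i, j, w in rg.edges:
    print(f"  edge {i}-{j}  weight {w}  (1 + shared bonds)")
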