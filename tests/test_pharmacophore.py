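"""Pharmacophore typing and graph reduction, checked against hand reductions
and an independently coded brute-force oracle."""

import numpy as np
import pytest
from rdkit import Chem

from pharmgnn.molio import graph_from_mol, parse_molecule
from pharmgnn.pharmacophore import (
    FeatureCategory as F,
    RingCategory as R,
    SYMBOLS,
    enumerate_types,
    load_smarts_table,
    perceive_features,
    reduce_graph,
    reduce_smiles,
    resolve_feature,
)

# -- independent oracle ----------------------------------------------------
# A deliberately naive re-derivation: per-atom SMARTS matching, ring systems
# straight from RDKit ring info, union-find over same-category acyclic
# neighbours.  Shares no partitioning code with the implementation.


def _oracle_reduce(smiles):
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(Chem.MolFromSmiles(smiles)))
    evidence = {i: set() for i in range(mol.GetNumAtoms())}
    for cat, patt, _ in load_smarts_table():
        for match in mol.GetSubstructMatches(patt):
            for i in match:
                evidence[i].add(cat)

    def resolve(ev):
        if F.POS_IONIZABLE in ev:
            return F.POS_IONIZABLE
        if F.NEG_IONIZABLE in ev:
            return F.NEG_IONIZABLE
        if {F.DONOR, F.ACCEPTOR} <= ev:
            return F.DONOR_AND_ACCEPTOR
        if F.DONOR in ev:
            return F.DONOR
        if F.ACCEPTOR in ev:
            return F.ACCEPTOR
        return F.NO_FEATURE

    groups = []
    in_ring = set()
    for ring in mol.GetRingInfo().AtomRings():
        in_ring |= set(ring)
        aromatic = all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
        cat = R.AROMATIC_RING if aromatic else R.ALIPHATIC_RING
        pooled = set().union(*(evidence[i] for i in ring))
        groups.append((cat, resolve(pooled), frozenset(ring)))

    # union-find over acyclic atoms with equal resolved categories
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    acyclic = [i for i in range(mol.GetNumAtoms()) if i not in in_ring]
    for i in acyclic:
        parent[i] = i
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in parent and j in parent and resolve(evidence[i]) == resolve(evidence[j]):
            parent[find(i)] = find(j)
    comps = {}
    for i in acyclic:
        comps.setdefault(find(i), set()).add(i)
    for members in comps.values():
        any_atom = next(iter(members))
        groups.append((R.ACYCLIC, resolve(evidence[any_atom]), frozenset(members)))

    # edges: any bond across two groups; weight 1 + bonds inside both
    edges = {}
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        for gi, (_, _, ga) in enumerate(groups):
            for gj, (_, _, gb) in enumerate(groups):
                if gi >= gj:
                    continue
                crosses = (i in ga and j in gb) or (j in ga and i in gb)
                inside_both = {i, j} <= ga and {i, j} <= gb
                if crosses or inside_both:
                    edges.setdefault((gi, gj), 1)
                    if inside_both:
                        edges[(gi, gj)] += 1
    multiset = tuple(sorted((cat, feat) for cat, feat, _ in groups))
    return multiset, edges, groups


# -- type enumeration ------------------------------------------------------

def test_eighteen_types_from_three_by_six():
    types = enumerate_types()
    assert len(types) == 18
    assert len({(t.ring, t.feature) for t in types}) == 18
    assert sum(t.ring == R.AROMATIC_RING for t in types) == 6
    assert len({t.symbol for t in types}) == 18


def test_published_symbol_aliases():
    assert SYMBOLS[(R.ALIPHATIC_RING, F.POS_IONIZABLE)] == "Y"
    assert SYMBOLS[(R.ACYCLIC, F.DONOR)] == "Co"
    assert SYMBOLS[(R.AROMATIC_RING, F.DONOR)] == "Ti"
    assert SYMBOLS[(R.ACYCLIC, F.ACCEPTOR)] == "Ni"
    assert SYMBOLS[(R.AROMATIC_RING, F.NO_FEATURE)] == "Sc"


# -- feature perception and priority --------------------------------------

def test_carboxylic_acid_oxygen_is_negative_ionizable():
    g = parse_molecule("CC(=O)O")
    ev = perceive_features(g)
    oxygens = [i for i, a in enumerate(g.atoms) if a.element == "O"]
    assert all(F.NEG_IONIZABLE in ev[i] for i in oxygens)


def test_aliphatic_amine_is_positive_ionizable():
    g = parse_molecule("CCN")
    ev = perceive_features(g)
    n = next(i for i, a in enumerate(g.atoms) if a.element == "N")
    assert F.POS_IONIZABLE in ev[n]


def test_methane_has_no_evidence():
    assert perceive_features(parse_molecule("C")) == [set()]


@pytest.mark.parametrize(
    "evidence, expected",
    [
        ({F.DONOR, F.ACCEPTOR}, F.DONOR_AND_ACCEPTOR),
        ({F.DONOR, F.ACCEPTOR, F.POS_IONIZABLE}, F.POS_IONIZABLE),
        ({F.NEG_IONIZABLE, F.DONOR}, F.NEG_IONIZABLE),
        ({F.ACCEPTOR}, F.ACCEPTOR),
        (set(), F.NO_FEATURE),
    ],
)
def test_priority_resolution(evidence, expected):
    assert resolve_feature(evidence) == expected


# -- hand-reduced reference molecules --------------------------------------

def test_benzene_single_aromatic_featureless_node():
    rg = reduce_smiles("c1ccccc1")
    assert rg.n_nodes == 1
    assert rg.nodes[0].type.symbol == "Sc"
    assert rg.single_pharmacophore


def test_naphthalene_two_nodes_fusion_weight_two():
    rg = reduce_smiles("c1ccc2ccccc2c1")
    assert [n.type.symbol for n in rg.nodes] == ["Sc", "Sc"]
    assert rg.edges == [(0, 1, 2)]


def test_biphenyl_connecting_bond_weight_one():
    rg = reduce_smiles("c1ccccc1-c1ccccc1")
    assert [n.type.symbol for n in rg.nodes] == ["Sc", "Sc"]
    assert rg.edges == [(0, 1, 1)]


def test_ethane_single_pharmacophore_flag():
    rg = reduce_smiles("CC")
    assert rg.n_nodes == 1 and rg.single_pharmacophore


def test_ethanol_partition_and_types():
    rg = reduce_smiles("CCO")
    by_symbol = {n.type.symbol: sorted(n.member_atoms) for n in rg.nodes}
    assert set(by_symbol) == {"Ge", "Ga"}  # CC featureless run + hydroxyl D&A
    assert len(by_symbol["Ge"]) == 2 and len(by_symbol["Ga"]) == 1


def test_pyrrole_is_aromatic_donor_node():
    rg = reduce_smiles("c1cc[nH]c1")
    assert rg.nodes[0].type.symbol == "Ti"


def test_fusion_atoms_belong_to_both_rings():
    rg = reduce_smiles("c1ccc2ccccc2c1")
    shared = rg.nodes[0].member_atoms & rg.nodes[1].member_atoms
    assert len(shared) == 2
    for a in shared:
        assert sorted(rg.membership[a]) == [0, 1]


def test_spiro_rings_connected_without_fusion_bond():
    rg = reduce_smiles("C1CCC2(CC1)CCCCC2")
    assert rg.n_nodes == 2
    assert rg.edges == [(0, 1, 1)]
    assert rg.is_connected()


# -- library-level invariants ----------------------------------------------

def test_reduction_matches_generation_ground_truth(library200):
    for rec in library200:
        assert reduce_smiles(rec.smiles).type_multiset() == rec.node_types


def test_every_heavy_atom_covered(library200, graphs200):
    for g in graphs200:
        rg = reduce_graph(g)
        covered = set().union(*(n.member_atoms for n in rg.nodes))
        assert covered == set(range(g.n_atoms))


def test_connected_molecules_give_connected_rgs(graphs200):
    for g in graphs200:
        assert reduce_graph(g).is_connected()


def test_oracle_equivalence_on_library(library200):
    """Node-type multiset and weighted edge multiset agree with the naive
    atom-by-atom oracle on all 200 packaged molecules."""
    for rec in library200:
        rg = reduce_smiles(rec.smiles)
        oracle_multiset, oracle_edges, oracle_groups = _oracle_reduce(rec.smiles)
        assert rg.type_multiset() == oracle_multiset
        # compare edges as multisets of (type_i, type_j, weight)
        def canon(edge_map, groups):
            out = []
            for (i, j), w in edge_map.items():
                ti, tj = groups[i][:2], groups[j][:2]
                out.append((tuple(sorted([ti, tj])), w))
            return sorted(out)
        impl_edges = {
            (i, j): w for i, j, w in rg.edges
        }
        impl_groups = [(n.type.ring, n.type.feature, n.member_atoms) for n in rg.nodes]
        assert canon(impl_edges, impl_groups) == canon(oracle_edges, oracle_groups)


def test_reduction_invariant_to_atom_order(library200):
    rng = np.random.default_rng(0)
    for rec in library200[:30]:
        mol = Chem.MolFromSmiles(rec.smiles)
        perm = [int(x) for x in rng.permutation(mol.GetNumAtoms())]
        renumbered = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
        rg_a = reduce_smiles(rec.smiles)
        rg_b = reduce_smiles(renumbered)
        assert rg_a.type_multiset() == rg_b.type_multiset()
        assert sorted(w for _, _, w in rg_a.edges) == sorted(w for _, _, w in rg_b.edges)


def test_malformed_smarts_table_rejected(tmp_path):
    bad = tmp_path / "rules.tsv"
    bad.write_text("DONOR\t[NX3(((\tbroken\n")
    from pharmgnn.molio import ConfigurationError

    with pytest.raises(ConfigurationError):
        load_smarts_table(bad)


def test_export_serialization_roundtrip():
    import json

    rg = reduce_smiles("CC(=O)Nc1ccccc1")
    payload = json.loads(rg.to_json())
    assert len(payload["nodes"]) == rg.n_nodes
    assert payload["single_pharmacophore"] is False
    assert all(e["weight"] >= 1 for e in payload["edges"])
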