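"""Pharmacophore-based graph reduction.

A molecule's heavy-atom graph is collapsed into a *reduced graph* (RG) whose
nodes are pharmacophore-typed atom groups and whose edges preserve the parent
topology.  Each node carries one of 18 types: the product of three ring
categories (aromatic ring > aliphatic ring > acyclic, in priority order) and
six feature categories (positively ionizable > negatively ionizable > joint
donor/acceptor > donor > acceptor > no feature).

Grouping rules frozen here:

* every smallest-set-of-smallest-rings ring is one group; fused rings are
  separate groups whose shared (fusion) bonds raise the RG edge weight —
  an RG edge weighs ``1 + number of bonds shared by both groups``;
* contiguous acyclic atoms with the same resolved feature category merge into
  one group; featureless linkers form their own no-feature groups;
* exocyclic substituent atoms (e.g. a phenol oxygen) form acyclic groups of
  their own rather than joining the ring group.

Feature evidence comes from the SMARTS table shipped in
``data/pharmacophore_smarts.tsv`` (editable, swappable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources

from rdkit import Chem

from .molio import ConfigurationError, MolecularGraph, parse_molecule


class RingCategory(IntEnum):
    """Ring status of an atom group; enum order is priority, high to low."""

    AROMATIC_RING = 0
    ALIPHATIC_RING = 1
    ACYCLIC = 2


class FeatureCategory(IntEnum):
    """Pharmacophoric feature; enum order is priority, high to low."""

    POS_IONIZABLE = 0
    NEG_IONIZABLE = 1
    DONOR_AND_ACCEPTOR = 2
    DONOR = 3
    ACCEPTOR = 4
    NO_FEATURE = 5


# Two-letter element-symbol aliases for the 18 (ring, feature) pairs.  The
# five aliases fixed by the naming scheme this follows: Y = aliphatic/pos-
# ionizable, Co = acyclic/donor, Ti = aromatic/donor, Ni = acyclic/acceptor,
# Sc = aromatic/no-feature.  The rest are package-assigned, all distinct.
SYMBOLS: dict[tuple[RingCategory, FeatureCategory], str] = {
    (RingCategory.AROMATIC_RING, FeatureCategory.POS_IONIZABLE): "Mn",
    (RingCategory.AROMATIC_RING, FeatureCategory.NEG_IONIZABLE): "Fe",
    (RingCategory.AROMATIC_RING, FeatureCategory.DONOR_AND_ACCEPTOR): "Cr",
    (RingCategory.AROMATIC_RING, FeatureCategory.DONOR): "Ti",
    (RingCategory.AROMATIC_RING, FeatureCategory.ACCEPTOR): "V",
    (RingCategory.AROMATIC_RING, FeatureCategory.NO_FEATURE): "Sc",
    (RingCategory.ALIPHATIC_RING, FeatureCategory.POS_IONIZABLE): "Y",
    (RingCategory.ALIPHATIC_RING, FeatureCategory.NEG_IONIZABLE): "Zr",
    (RingCategory.ALIPHATIC_RING, FeatureCategory.DONOR_AND_ACCEPTOR): "Nb",
    (RingCategory.ALIPHATIC_RING, FeatureCategory.DONOR): "Mo",
    (RingCategory.ALIPHATIC_RING, FeatureCategory.ACCEPTOR): "Tc",
    (RingCategory.ALIPHATIC_RING, FeatureCategory.NO_FEATURE): "Ru",
    (RingCategory.ACYCLIC, FeatureCategory.POS_IONIZABLE): "Cu",
    (RingCategory.ACYCLIC, FeatureCategory.NEG_IONIZABLE): "Zn",
    (RingCategory.ACYCLIC, FeatureCategory.DONOR_AND_ACCEPTOR): "Ga",
    (RingCategory.ACYCLIC, FeatureCategory.DONOR): "Co",
    (RingCategory.ACYCLIC, FeatureCategory.ACCEPTOR): "Ni",
    (RingCategory.ACYCLIC, FeatureCategory.NO_FEATURE): "Ge",
}


@dataclass(frozen=True, order=True)
class PharmacophoreType:
    ring: RingCategory
    feature: FeatureCategory

    @property
    def symbol(self) -> str:
        return SYMBOLS[(self.ring, self.feature)]

    def __str__(self) -> str:
        return f"{self.symbol}({self.ring.name.lower()},{self.feature.name.lower()})"


def enumerate_types() -> list[PharmacophoreType]:
    """All 18 pharmacophore node types (3 ring x 6 feature categories)."""
    return [PharmacophoreType(r, f) for r in RingCategory for f in FeatureCategory]


@dataclass
class PharmacophoreNode:
    type: PharmacophoreType
    member_atoms: frozenset[int]

    def __post_init__(self):
        if not self.member_atoms:
            raise ValueError("pharmacophore node with no member atoms")


@dataclass
class ReducedGraph:
    """RG = (V', E') with weighted edges and an atom -> node multi-map."""

    nodes: list[PharmacophoreNode]
    edges: list[tuple[int, int, int]]  # (node_i, node_j, weight), i < j
    membership: dict[int, list[int]]
    single_pharmacophore: bool = field(default=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def type_multiset(self) -> tuple[tuple[RingCategory, FeatureCategory], ...]:
        return tuple(sorted((n.type.ring, n.type.feature) for n in self.nodes))

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def is_connected(self) -> bool:
        if self.n_nodes <= 1:
            return True
        seen = {0}
        stack = [0]
        while stack:
            for nb in self.neighbors(stack.pop()):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == self.n_nodes

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "symbol": n.type.symbol,
                    "ring": n.type.ring.name,
                    "feature": n.type.feature.name,
                    "member_atoms": sorted(n.member_atoms),
                }
                for n in self.nodes
            ],
            "edges": [{"i": i, "j": j, "weight": w} for i, j, w in self.edges],
            "single_pharmacophore": self.single_pharmacophore,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# -- SMARTS rule table ------------------------------------------------------

_RAW_CATEGORIES = {
    "POS_IONIZABLE": FeatureCategory.POS_IONIZABLE,
    "NEG_IONIZABLE": FeatureCategory.NEG_IONIZABLE,
    "DONOR": FeatureCategory.DONOR,
    "ACCEPTOR": FeatureCategory.ACCEPTOR,
}


def load_smarts_table(path=None) -> list[tuple[FeatureCategory, Chem.Mol, str]]:
    """Load and compile the feature-perception SMARTS table.

    Malformed patterns raise a configuration error at load time rather than
    silently matching nothing.
    """
    if path is None:
        text = resources.files("pharmgnn.data").joinpath("pharmacophore_smarts.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ConfigurationError(f"SMARTS table line {lineno}: expected <category>\\t<pattern>")
        cat_name, smarts = parts[0], parts[1]
        if cat_name not in _RAW_CATEGORIES:
            raise ConfigurationError(f"SMARTS table line {lineno}: unknown category {cat_name!r}")
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ConfigurationError(f"SMARTS table line {lineno}: malformed SMARTS {smarts!r}")
        table.append((_RAW_CATEGORIES[cat_name], patt, smarts))
    return table


_DEFAULT_TABLE: list[tuple[FeatureCategory, Chem.Mol, str]] | None = None


def _default_table():
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_smarts_table()
    return _DEFAULT_TABLE


def perceive_features(
    graph: MolecularGraph, table=None
) -> list[set[FeatureCategory]]:
    """Raw per-atom feature evidence (an atom may match several categories)."""
    table = table if table is not None else _default_table()
    evidence: list[set[FeatureCategory]] = [set() for _ in range(graph.n_atoms)]
    for category, patt, _ in table:
        for match in graph.mol.GetSubstructMatches(patt, uniquify=True):
            for idx in match:
                evidence[idx].add(category)
    return evidence


def resolve_feature(evidence: set[FeatureCategory]) -> FeatureCategory:
    """Priority resolution of an evidence set into a single feature category.

    Joint donor/acceptor arises when both donor and acceptor evidence are
    present and outranks either alone.
    """
    if FeatureCategory.POS_IONIZABLE in evidence:
        return FeatureCategory.POS_IONIZABLE
    if FeatureCategory.NEG_IONIZABLE in evidence:
        return FeatureCategory.NEG_IONIZABLE
    has_d = FeatureCategory.DONOR in evidence
    has_a = FeatureCategory.ACCEPTOR in evidence
    if (has_d and has_a) or FeatureCategory.DONOR_AND_ACCEPTOR in evidence:
        return FeatureCategory.DONOR_AND_ACCEPTOR
    if has_d:
        return FeatureCategory.DONOR
    if has_a:
        return FeatureCategory.ACCEPTOR
    return FeatureCategory.NO_FEATURE


@dataclass
class AtomGroup:
    atoms: frozenset[int]
    ring: RingCategory


def partition_atoms(
    graph: MolecularGraph, evidence: list[set[FeatureCategory]] | None = None
) -> list[AtomGroup]:
    """Partition heavy atoms into ring groups and acyclic feature runs.

    Ring groups come one per SSSR ring (fusion atoms belong to every ring
    containing them).  Remaining acyclic atoms are grouped into maximal
    connected runs sharing the same per-atom resolved feature category.
    """
    if evidence is None:
        evidence = perceive_features(graph)
    mol = graph.mol
    groups: list[AtomGroup] = []
    ring_atoms: set[int] = set()
    for ring in Chem.GetSymmSSSR(mol):
        atoms = frozenset(ring)
        ring_atoms |= atoms
        aromatic = all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
        groups.append(
            AtomGroup(atoms, RingCategory.AROMATIC_RING if aromatic else RingCategory.ALIPHATIC_RING)
        )
    # acyclic runs: connected components of same-category acyclic atoms
    acyclic = [i for i in range(graph.n_atoms) if i not in ring_atoms]
    category = {i: resolve_feature(evidence[i]) for i in acyclic}
    unvisited = set(acyclic)
    adjacency: dict[int, list[int]] = {i: [] for i in acyclic}
    for a, b, _ in graph.bonds:
        if a in adjacency and b in adjacency:
            adjacency[a].append(b)
            adjacency[b].append(a)
    for start in sorted(acyclic):
        if start not in unvisited:
            continue
        component = {start}
        unvisited.discard(start)
        stack = [start]
        while stack:
            cur = stack.pop()
            for nb in adjacency[cur]:
                if nb in unvisited and category[nb] == category[start]:
                    unvisited.discard(nb)
                    component.add(nb)
                    stack.append(nb)
        groups.append(AtomGroup(frozenset(component), RingCategory.ACYCLIC))
    return groups


def resolve_type(
    group: AtomGroup, evidence: list[set[FeatureCategory]]
) -> PharmacophoreType:
    """Resolve a group to its pharmacophore type.

    Ring category is the group's own (highest-priority ring status present);
    the feature category priority-resolves the union of member-atom evidence.
    """
    pooled: set[FeatureCategory] = set()
    for i in group.atoms:
        pooled |= evidence[i]
    return PharmacophoreType(group.ring, resolve_feature(pooled))


def reduce_graph(
    graph: MolecularGraph, evidence: list[set[FeatureCategory]] | None = None
) -> ReducedGraph:
    """Collapse a molecular graph into its pharmacophore reduced graph.

    An RG edge joins two groups whenever a chemical bond connects them (this
    includes ring-fusion bonds); the edge weight is one plus the number of
    bonds whose both endpoints belong to both groups, so biphenyl's inter-ring
    bond weighs 1 while naphthalene's fusion raises the weight to 2.
    """
    if evidence is None:
        evidence = perceive_features(graph)
    groups = partition_atoms(graph, evidence)
    nodes = [PharmacophoreNode(resolve_type(g, evidence), g.atoms) for g in groups]
    membership: dict[int, list[int]] = {}
    for ni, node in enumerate(nodes):
        for a in node.member_atoms:
            membership.setdefault(a, []).append(ni)
    adjacent: set[tuple[int, int]] = set()
    shared: dict[tuple[int, int], int] = {}
    for a, b, _ in graph.bonds:
        for na in membership[a]:
            for nb in membership[b]:
                if na == nb:
                    continue
                key = (min(na, nb), max(na, nb))
                adjacent.add(key)
        both = set(membership[a]) & set(membership[b])
        for na in both:
            for nb in both:
                if na < nb:
                    shared[(na, nb)] = shared.get((na, nb), 0) + 1
                    adjacent.add((na, nb))
    edges = [(i, j, 1 + shared.get((i, j), 0)) for i, j in sorted(adjacent)]
    return ReducedGraph(
        nodes=nodes,
        edges=edges,
        membership=membership,
        single_pharmacophore=len(nodes) == 1,
    )


def reduce_smiles(smiles: str) -> ReducedGraph:
    """Convenience: parse a SMILES string and reduce it."""
    return reduce_graph(parse_molecule(smiles))
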