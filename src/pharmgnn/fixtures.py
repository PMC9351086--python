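"""Synthetic molecule libraries with known pharmacophore composition.

Molecules are assembled by attaching feature-bearing substituents (and
optionally a second ring system) to ring scaffolds drawn from hand-curated
pools.  Each pool fragment is tagged with the pharmacophore node types it
contributes, so every generated molecule carries a generation-time
ground-truth node-type multiset that is derived from the tags alone —
independent of the reduction code it is later used to test.

Pool design constraints that keep the tags exact:

* substituents attach only to ring carbons bearing hydrogen, so no scaffold
  heteroatom feature is ever destroyed by substitution;
* substituents never bond to each other directly (they connect through ring
  atoms), so their acyclic groups never merge;
* ambiguous multi-feature groups are excluded from the pools and exercised by
  dedicated priority-resolution unit tests instead.

Synthetic labels are either linear in ground-truth type counts plus Gaussian
noise (regression) or the indicator of a target type's presence
(classification).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from rdkit import Chem

from .molio import LabeledDataset, parse_molecule
from .pharmacophore import FeatureCategory as F
from .pharmacophore import RingCategory as R

TypeKey = tuple[R, F]


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PoolFragment:
    """A pool entry: SMILES plus the node types it contributes on attachment."""

    smiles: str
    node_types: tuple[TypeKey, ...]
    # ring categories of scaffolds this substituent may attach to (None = any);
    # used for context-sensitive groups such as an amino substituent, whose
    # feature depends on whether it sits on an aromatic or aliphatic ring.
    allowed_rings: tuple[R, ...] | None = None


SCAFFOLD_POOL: tuple[PoolFragment, ...] = (
    PoolFragment("c1ccccc1", ((R.AROMATIC_RING, F.NO_FEATURE),)),
    PoolFragment("c1ccncc1", ((R.AROMATIC_RING, F.ACCEPTOR),)),
    PoolFragment("c1cc[nH]c1", ((R.AROMATIC_RING, F.DONOR),)),
    PoolFragment("c1cc[nH]n1", ((R.AROMATIC_RING, F.DONOR_AND_ACCEPTOR),)),
    PoolFragment("c1c[nH]cn1", ((R.AROMATIC_RING, F.POS_IONIZABLE),)),
    PoolFragment("c1nnn[nH]1", ((R.AROMATIC_RING, F.NEG_IONIZABLE),)),
    PoolFragment("C1CCCCC1", ((R.ALIPHATIC_RING, F.NO_FEATURE),)),
    PoolFragment("C1CCOCC1", ((R.ALIPHATIC_RING, F.ACCEPTOR),)),
    PoolFragment("C1CCNCC1", ((R.ALIPHATIC_RING, F.POS_IONIZABLE),)),
    PoolFragment(
        "O=C1CCCN1",
        ((R.ALIPHATIC_RING, F.DONOR), (R.ACYCLIC, F.ACCEPTOR)),
    ),
    PoolFragment(
        "O=C1COCCN1",
        ((R.ALIPHATIC_RING, F.DONOR_AND_ACCEPTOR), (R.ACYCLIC, F.ACCEPTOR)),
    ),
    PoolFragment(
        "O=C1CCC(=O)N1",
        ((R.ALIPHATIC_RING, F.NEG_IONIZABLE), (R.ACYCLIC, F.ACCEPTOR), (R.ACYCLIC, F.ACCEPTOR)),
    ),
)

SUBSTITUENT_POOL: tuple[PoolFragment, ...] = (
    # attachment atom is always atom 0 of the fragment SMILES
    PoolFragment("C", ((R.ACYCLIC, F.NO_FEATURE),)),
    PoolFragment("CC", ((R.ACYCLIC, F.NO_FEATURE),)),
    PoolFragment("O", ((R.ACYCLIC, F.DONOR_AND_ACCEPTOR),)),
    PoolFragment("OC", ((R.ACYCLIC, F.ACCEPTOR), (R.ACYCLIC, F.NO_FEATURE))),
    PoolFragment("C#N", ((R.ACYCLIC, F.NO_FEATURE), (R.ACYCLIC, F.ACCEPTOR))),
    PoolFragment("C(=O)O", ((R.ACYCLIC, F.NEG_IONIZABLE),)),
    PoolFragment("CCN", ((R.ACYCLIC, F.NO_FEATURE), (R.ACYCLIC, F.POS_IONIZABLE))),
    PoolFragment(
        "NC(C)=O",
        ((R.ACYCLIC, F.DONOR), (R.ACYCLIC, F.NO_FEATURE), (R.ACYCLIC, F.ACCEPTOR)),
    ),
    # aromatic-only: on an aromatic ring this is an aniline-type donor; on an
    # aliphatic ring it would become a positively ionizable amine instead.
    PoolFragment("N", ((R.ACYCLIC, F.DONOR),), allowed_rings=(R.AROMATIC_RING,)),
    PoolFragment("F", ((R.ACYCLIC, F.NO_FEATURE),)),
)


@dataclass(frozen=True)
class RegressionRule:
    """label = sum over 18 types of coefficient * type count, + N(0, sigma)."""

    coefficients: dict[TypeKey, float]
    sigma: float = 0.1


@dataclass(frozen=True)
class ClassificationRule:
    """label = 1 iff the ground-truth multiset contains the target type."""

    target: TypeKey = (R.AROMATIC_RING, F.DONOR)


def default_regression_rule(seed: int = 0, sigma: float = 0.1) -> RegressionRule:
    rng = np.random.default_rng(seed)
    keys = [(r, f) for r in R for f in F]
    return RegressionRule(
        coefficients={k: float(c) for k, c in zip(keys, rng.normal(0.0, 1.0, len(keys)))},
        sigma=sigma,
    )


@dataclass
class FixtureSpec:
    n_molecules: int = 200
    seed: int = 7
    scaffolds: tuple[PoolFragment, ...] = SCAFFOLD_POOL
    substituents: tuple[PoolFragment, ...] = SUBSTITUENT_POOL
    label_rule: RegressionRule | ClassificationRule | None = None
    p_second_ring: float = 0.35
    min_substituents: int = 1
    max_substituents: int = 3
    max_retries: int = 30

    def __post_init__(self):
        if isinstance(self.label_rule, RegressionRule) and self.label_rule.sigma < 0:
            raise ValueError("noise sigma must be non-negative")


@dataclass
class FixtureRecord:
    smiles: str
    node_types: tuple[TypeKey, ...]  # sorted ground-truth multiset
    label: float | None = None


def _attachable_carbons(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and a.IsInRing() and a.GetTotalNumHs() >= 1
    ]


def _attach(mol: Chem.Mol, frag: Chem.Mol, mol_idx: int, frag_idx: int) -> Chem.Mol:
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(mol_idx, mol.GetNumAtoms() + frag_idx, Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


def _assemble(spec: FixtureSpec, scaffold: PoolFragment, rng: np.random.Generator,
              forced_substituent: PoolFragment | None) -> tuple[str, tuple[TypeKey, ...]]:
    mol = Chem.MolFromSmiles(scaffold.smiles)
    types: list[TypeKey] = list(scaffold.node_types)
    ring_cats = {t[0] for t in scaffold.node_types}

    if rng.random() < spec.p_second_ring:
        second = spec.scaffolds[rng.integers(len(spec.scaffolds))]
        frag = Chem.MolFromSmiles(second.smiles)
        spots_a, spots_b = _attachable_carbons(mol), _attachable_carbons(frag)
        if spots_a and spots_b:
            mol = _attach(mol, frag, spots_a[rng.integers(len(spots_a))],
                          spots_b[rng.integers(len(spots_b))])
            types.extend(second.node_types)
            ring_cats |= {t[0] for t in second.node_types}

    n_sub = int(rng.integers(spec.min_substituents, spec.max_substituents + 1))
    chosen: list[PoolFragment] = []
    if forced_substituent is not None:
        chosen.append(forced_substituent)
    while len(chosen) < n_sub:
        cand = spec.substituents[rng.integers(len(spec.substituents))]
        if cand.allowed_rings is not None and not (set(cand.allowed_rings) & ring_cats):
            continue
        chosen.append(cand)
    for sub in chosen:
        spots = _attachable_carbons(mol)
        if not spots:
            break
        if sub.allowed_rings is not None:
            # restrict to ring atoms of an allowed aromaticity
            spots = [
                i for i in spots
                if (mol.GetAtomWithIdx(i).GetIsAromatic()
                    and R.AROMATIC_RING in sub.allowed_rings)
                or (not mol.GetAtomWithIdx(i).GetIsAromatic()
                    and R.ALIPHATIC_RING in sub.allowed_rings)
            ]
            if not spots:
                continue
        frag = Chem.MolFromSmiles(sub.smiles)
        mol = _attach(mol, frag, spots[rng.integers(len(spots))], 0)
        types.extend(sub.node_types)
    return Chem.MolToSmiles(mol), tuple(sorted(types))


def generate_library(spec: FixtureSpec) -> list[FixtureRecord]:
    """Generate ``spec.n_molecules`` records, deterministic under the seed.

    The first molecules cycle through every scaffold and force every
    substituent once (stratified coverage), so all 18 node types appear in any
    library of at least ~20 molecules.  Duplicate SMILES trigger bounded
    resampling; assembly failures likewise.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[FixtureRecord] = []
    seen: set[str] = set()
    for i in range(spec.n_molecules):
        scaffold = spec.scaffolds[i % len(spec.scaffolds)]
        forced = spec.substituents[i % len(spec.substituents)] if i < len(spec.substituents) else None
        if forced is not None and forced.allowed_rings is not None:
            if not (set(forced.allowed_rings) & {t[0] for t in scaffold.node_types}):
                forced = None
        smiles = None
        types: tuple[TypeKey, ...] = ()
        for attempt in range(spec.max_retries):
            try:
                smiles, types = _assemble(spec, scaffold, rng, forced)
            except Exception:
                continue
            if smiles not in seen:
                break
        if smiles is None:
            raise GenerationError(f"could not assemble molecule {i} from {scaffold.smiles}")
        seen.add(smiles)
        records.append(FixtureRecord(smiles=smiles, node_types=types))
    if isinstance(spec.label_rule, (RegressionRule, ClassificationRule)):
        records = synth_labels(records, spec.label_rule, spec.seed + 1)
    return records


def synth_labels(
    records: Sequence[FixtureRecord],
    rule: RegressionRule | ClassificationRule,
    seed: int,
) -> list[FixtureRecord]:
    """Attach synthetic labels derived from the ground-truth type multisets."""
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        if isinstance(rule, RegressionRule):
            y = sum(rule.coefficients.get(t, 0.0) for t in rec.node_types)
            y += rng.normal(0.0, rule.sigma) if rule.sigma > 0 else 0.0
        elif isinstance(rule, ClassificationRule):
            y = float(rule.target in rec.node_types)
        else:
            raise TypeError(f"unknown label rule {rule!r}")
        out.append(replace(rec, label=float(y)))
    return out


def to_dataset(records: Sequence[FixtureRecord], task_type: str) -> LabeledDataset:
    """Parse records into the standard labeled-dataset container."""
    pairs = []
    for rec in records:
        if rec.label is None:
            raise ValueError("records must be labeled; call synth_labels first")
        pairs.append((parse_molecule(rec.smiles), np.asarray([rec.label])))
    return LabeledDataset(records=pairs, task_type=task_type, n_tasks=1)


def default_library(n: int = 200, seed: int = 7) -> list[FixtureRecord]:
    """The packaged reference library configuration (unlabeled)."""
    return generate_library(FixtureSpec(n_molecules=n, seed=seed))
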