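"""Molecule parsing, standardization, featurization and labeled-dataset I/O.

Molecules enter the pipeline as SMILES strings and are represented as heavy-atom
graphs ``G = (V, E)`` with fixed-width one-hot/scalar feature encodings for
atoms and bonds.  Standardization (largest organic fragment, charge
neutralization, canonicalization) collapses duplicates to identical canonical
strings, mirroring common bioactivity-dataset curation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

FEATURE_VERSION = "1.0"  # frozen encoding; bump if any vocabulary changes

# Frozen featurization vocabularies.  Elements outside the list map to the
# trailing "other" slot (logged once per element).
ELEMENTS = ["B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"]
HYBRIDIZATIONS = ["SP", "SP2", "SP3", "SP3D", "SP3D2"]
CHIRALITIES = ["CHI_UNSPECIFIED", "CHI_TETRAHEDRAL_CW", "CHI_TETRAHEDRAL_CCW"]
MAX_DEGREE = 5
MAX_NUM_H = 4
BOND_TYPES = ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC"]
BOND_STEREO = ["STEREONONE", "STEREOZ", "STEREOE"]

ATOM_FEATURE_DIM = (
    len(ELEMENTS) + 1  # element one-hot (+other)
    + 1                # formal charge (scalar)
    + MAX_DEGREE + 2   # degree one-hot over 0..MAX_DEGREE (+other)
    + MAX_NUM_H + 2    # total-H one-hot over 0..MAX_NUM_H (+other)
    + len(HYBRIDIZATIONS) + 1
    + 1                # aromatic flag
    + len(CHIRALITIES) + 1
)
BOND_FEATURE_DIM = (
    len(BOND_TYPES) + 1  # bond-type one-hot (+other)
    + 1                  # conjugated flag
    + 1                  # in-ring flag
    + len(BOND_STEREO) + 1
)


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be turned into a heavy-atom graph."""

    def __init__(self, smiles: str, reason: str = "unparsable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


class StandardizationError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


class EmptyDatasetError(ValueError):
    pass


def _one_hot(value, vocab: Sequence) -> list[float]:
    """One-hot with a trailing 'other' slot; exactly one slot active."""
    vec = [0.0] * (len(vocab) + 1)
    try:
        vec[vocab.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


@dataclass(frozen=True)
class AtomFeatures:
    element: str
    formal_charge: int
    degree: int
    num_hydrogens: int
    hybridization: str
    is_aromatic: bool
    chirality: str

    def vector(self) -> np.ndarray:
        parts = (
            _one_hot(self.element, ELEMENTS)
            + [float(self.formal_charge)]
            + _one_hot(self.degree, list(range(MAX_DEGREE + 1)))
            + _one_hot(self.num_hydrogens, list(range(MAX_NUM_H + 1)))
            + _one_hot(self.hybridization, HYBRIDIZATIONS)
            + [1.0 if self.is_aromatic else 0.0]
            + _one_hot(self.chirality, CHIRALITIES)
        )
        return np.asarray(parts, dtype=np.float64)


@dataclass(frozen=True)
class BondFeatures:
    bond_type: str
    is_conjugated: bool
    is_in_ring: bool
    stereo: str

    def vector(self) -> np.ndarray:
        parts = (
            _one_hot(self.bond_type, BOND_TYPES)
            + [1.0 if self.is_conjugated else 0.0]
            + [1.0 if self.is_in_ring else 0.0]
            + _one_hot(self.stereo, BOND_STEREO)
        )
        return np.asarray(parts, dtype=np.float64)


@dataclass
class MolecularGraph:
    """Undirected heavy-atom graph with featurized atoms and bonds.

    Atom order is the toolkit's canonical order (the molecule is re-parsed from
    its canonical SMILES), so two SMILES spellings of one molecule yield
    identical graphs.
    """

    atoms: list[AtomFeatures]
    bonds: list[tuple[int, int, BondFeatures]]
    canonical_smiles: str
    mol: Chem.Mol = field(repr=False, compare=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out


def _atom_features(atom: Chem.Atom) -> AtomFeatures:
    elem = atom.GetSymbol()
    if elem not in ELEMENTS:
        log.info("element %s outside vocabulary; encoded as 'other'", elem)
    return AtomFeatures(
        element=elem,
        formal_charge=atom.GetFormalCharge(),
        degree=atom.GetDegree(),
        num_hydrogens=atom.GetTotalNumHs(),
        hybridization=str(atom.GetHybridization()),
        is_aromatic=atom.GetIsAromatic(),
        chirality=str(atom.GetChiralTag()),
    )


def _bond_features(bond: Chem.Bond) -> BondFeatures:
    return BondFeatures(
        bond_type=str(bond.GetBondType()),
        is_conjugated=bond.GetIsConjugated(),
        is_in_ring=bond.IsInRing(),
        stereo=str(bond.GetStereo()),
    )


def graph_from_mol(mol: Chem.Mol) -> MolecularGraph:
    """Build a graph from an RDKit Mol in its *current* atom order.

    ``parse_molecule`` is the canonical entry point; this exists for callers
    that need explicit control over atom numbering (e.g. equivariance checks).
    """
    atoms = [_atom_features(a) for a in mol.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _bond_features(b))
        for b in mol.GetBonds()
    ]
    return MolecularGraph(
        atoms=atoms, bonds=bonds, canonical_smiles=Chem.MolToSmiles(mol), mol=mol
    )


def parse_molecule(smiles: str) -> MolecularGraph:
    """Parse SMILES into a canonical-order heavy-atom graph."""
    if not smiles:
        raise MoleculeParseError(smiles, "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(smiles)
    if mol.GetNumHeavyAtoms() == 0:
        raise MoleculeParseError(smiles, "no heavy atoms")
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)  # re-parse: canonical atom order
    return graph_from_mol(mol)


_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_molecule(smiles: str) -> str:
    """Salt removal + neutralization + canonicalization.

    The largest fragment by heavy-atom count is kept (ties broken by molecular
    weight); charges are neutralized where a neutral form exists; the result is
    emitted as canonical SMILES so duplicates collapse to identical strings.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if not frags:
        raise MoleculeParseError(smiles, "no fragments")
    best = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Descriptors.MolWt(m)))
    neutral = _UNCHARGER.uncharge(best)
    if not any(a.GetAtomicNum() == 6 for a in neutral.GetAtoms()):
        raise StandardizationError(
            f"no carbon remains after salt stripping: {smiles!r}"
        )
    return Chem.MolToSmiles(neutral)


ACTIVITY_THRESHOLD_NM = 1000.0


def label_activity(potency_nM: float) -> str:
    """Binary activity call at the 1000 nM potency threshold.

    Boundary convention: a molecule is 'active' iff potency is strictly below
    1000 nM, so exactly 1000 nM is 'inactive'.
    """
    if not potency_nM > 0:
        raise ValueError(f"potency must be positive, got {potency_nM}")
    return "active" if potency_nM < ACTIVITY_THRESHOLD_NM else "inactive"


def featurize(graph: MolecularGraph) -> tuple[np.ndarray, np.ndarray]:
    """Stack atom and bond feature vectors into fixed-width matrices.

    Returns ``(X, E)`` with X of shape (n_atoms, ATOM_FEATURE_DIM) and E of
    shape (n_bonds, BOND_FEATURE_DIM), row-aligned with ``graph.bonds``.
    """
    X = np.stack([a.vector() for a in graph.atoms]) if graph.atoms else np.zeros((0, ATOM_FEATURE_DIM))
    if graph.bonds:
        E = np.stack([bf.vector() for _, _, bf in graph.bonds])
    else:
        E = np.zeros((0, BOND_FEATURE_DIM))
    return X, E


@dataclass
class LabeledDataset:
    """Parsed molecules with per-task labels (NaN marks a missing label)."""

    records: list[tuple[MolecularGraph, np.ndarray]]
    task_type: str  # "regression" | "classification"
    n_tasks: int

    def __post_init__(self):
        if self.task_type not in ("regression", "classification"):
            raise ConfigurationError(f"unknown task_type {self.task_type!r}")
        for _, y in self.records:
            if y.shape != (self.n_tasks,):
                raise ConfigurationError("label vector length != n_tasks")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def graphs(self) -> list[MolecularGraph]:
        return [g for g, _ in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.stack([y for _, y in self.records]) if self.records else np.zeros((0, self.n_tasks))

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset(
            records=[self.records[i] for i in indices],
            task_type=self.task_type,
            n_tasks=self.n_tasks,
        )


def read_dataset(
    path,
    smiles_column: str = "smiles",
    label_columns: Sequence[str] | None = None,
    task_type: str = "regression",
) -> LabeledDataset:
    """Read a CSV of SMILES + labels, standardizing and deduplicating rows.

    Rows whose SMILES fail to parse or standardize are dropped and counted in
    the log; duplicate canonical SMILES keep the first occurrence.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyDatasetError(f"no rows in {path}")
    if smiles_column not in df.columns:
        raise ConfigurationError(f"missing SMILES column {smiles_column!r} in {path}")
    if label_columns is None:
        label_columns = [c for c in df.columns if c != smiles_column]
    for c in label_columns:
        if c not in df.columns:
            raise ConfigurationError(f"missing label column {c!r} in {path}")

    records: list[tuple[MolecularGraph, np.ndarray]] = []
    seen: set[str] = set()
    n_dropped = n_dup = 0
    for _, row in df.iterrows():
        try:
            canonical = standardize_molecule(str(row[smiles_column]))
            graph = parse_molecule(canonical)
        except (MoleculeParseError, StandardizationError):
            n_dropped += 1
            continue
        if graph.canonical_smiles in seen:
            n_dup += 1
            continue
        seen.add(graph.canonical_smiles)
        y = np.asarray([pd.to_numeric(row[c], errors="coerce") for c in label_columns], dtype=np.float64)
        if task_type == "classification":
            bad = y[np.isfinite(y) & ~np.isin(y, (0.0, 1.0))]
            if bad.size:
                raise ConfigurationError(f"classification labels must be 0/1, got {bad[0]}")
        records.append((graph, y))
    if n_dropped or n_dup:
        log.warning("read_dataset: dropped %d unparsable rows, %d duplicates", n_dropped, n_dup)
    if not records:
        raise EmptyDatasetError(f"no valid molecules in {path}")
    return LabeledDataset(records=records, task_type=task_type, n_tasks=len(label_columns))


def write_dataset(path, smiles: Sequence[str], labels: np.ndarray, label_columns: Sequence[str]) -> None:
    labels = np.atleast_2d(np.asarray(labels, dtype=np.float64))
    if labels.shape[0] != len(smiles):
        labels = labels.T
    df = pd.DataFrame({"smiles": list(smiles)})
    for j, c in enumerate(label_columns):
        df[c] = labels[:, j]
    df.to_csv(path, index=False)
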