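"""Model interpretation: task-learned fingerprints, pharmacophore importance
and self-organizing-map projection.

A trained network yields three interpretable artifacts:

* the molecule embedding ``h_mol`` — a *task-learned fingerprint* usable as a
  descriptor;
* the readout attention weights — how much each pharmacophore node
  contributed to the molecule embedding, i.e. a per-pharmacophore importance;
* a 2-D self-organizing map of the fingerprints, where neurons holding both
  active and inactive molecules ("conflict neurons") mark the decision
  boundary region.

The SOM here is the batch variant: each epoch assigns every point to its
best-matching unit (Euclidean distance) and replaces every codebook vector by
the neighborhood-weighted mean of its assigned points, with a Gaussian
neighborhood whose radius decays over epochs.  The batch rule is
deterministic given the seed and drives the quantization error down
monotonically in practice (it degenerates to k-means as the radius shrinks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .molio import MolecularGraph
from .network import RGMPNN, make_batch, prepare_molecule


@dataclass
class FingerprintMatrix:
    """Task-learned fingerprints, one row per molecule in input order."""

    values: np.ndarray                      # (n_molecules, hidden_dim)
    ids: list[str]                          # canonical SMILES (or caller ids)
    labels: np.ndarray | None = None        # optional per-molecule labels

    def __post_init__(self):
        if self.values.shape[0] != len(self.ids):
            raise ValueError("row count must equal molecule count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fingerprints contain non-finite entries")


@dataclass
class ImportanceReport:
    """Readout attention per pharmacophore node, sorted descending."""

    smiles: str
    entries: list[dict]          # symbol, ring, feature, member_atoms, weight
    single_pharmacophore: bool

    def total_weight(self) -> float:
        return float(sum(e["weight"] for e in self.entries))

    def mean_weight_by_type(self) -> dict[str, float]:
        by_symbol: dict[str, list[float]] = {}
        for e in self.entries:
            by_symbol.setdefault(e["symbol"], []).append(e["weight"])
        return {s: float(np.mean(w)) for s, w in by_symbol.items()}


def extract_fingerprints(
    model: RGMPNN,
    graphs: Sequence[MolecularGraph],
    labels: np.ndarray | None = None,
    batch_size: int = 64,
) -> FingerprintMatrix:
    """One ``h_mol`` row per molecule, in input order."""
    rows = []
    for start in range(0, len(graphs), batch_size):
        chunk = [prepare_molecule(g) for g in graphs[start : start + batch_size]]
        result = model.forward(make_batch(chunk), training=False)
        rows.append(result.h_mol.data)
    values = np.concatenate(rows) if rows else np.zeros((0, model.config.hidden_dim))
    return FingerprintMatrix(
        values=values,
        ids=[g.canonical_smiles for g in graphs],
        labels=None if labels is None else np.asarray(labels),
    )


def pharmacophore_importance(model: RGMPNN, graph: MolecularGraph) -> ImportanceReport:
    """Readout attention paired with node identities, sorted descending.

    The weights are exactly the readout-phase attention of the forward pass —
    no recomputation or renormalization is applied.
    """
    pred = model.predict([graph])[0]
    return ImportanceReport(
        smiles=graph.canonical_smiles,
        entries=pred.attention_report,
        single_pharmacophore=pred.single_pharmacophore,
    )


@dataclass
class SOMGrid:
    """A fitted rectangular SOM lattice with molecule assignments."""

    shape: tuple[int, int]
    codebook: np.ndarray          # (rows*cols, dim)
    assignments: np.ndarray       # best-matching unit index per molecule
    qe_history: list[float]       # mean BMU distance per epoch
    labels: np.ndarray | None = None
    label_mix: dict[int, dict] = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.shape[0] * self.shape[1]

    def neuron_position(self, idx: int) -> tuple[int, int]:
        return divmod(idx, self.shape[1])

    def occupied_neurons(self) -> np.ndarray:
        return np.unique(self.assignments)

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "assignments": self.assignments.tolist(),
            "qe_history": [float(q) for q in self.qe_history],
            "label_mix": {
                str(k): v for k, v in sorted(self.label_mix.items())
            },
        }


def som_fit(
    fingerprints: FingerprintMatrix | np.ndarray,
    shape: tuple[int, int] = (10, 10),
    n_epochs: int = 200,
    seed: int = 0,
    sigma0: float = 1.5,
    sigma_end: float = 0.2,
    labels: np.ndarray | None = None,
    init: str = "pca",
) -> SOMGrid:
    """Fit a batch SOM to fingerprint rows; deterministic under the seed.

    The Gaussian neighborhood radius decays exponentially from ``sigma0`` to
    ``sigma_end`` over the epochs.  The default initialization lays the
    codebook out on the plane of the first two principal components, so the
    lattice is topographically ordered from the start and each batch update
    (a neighborhood-smoothed k-means step) drives the quantization error
    down monotonically; ``init="sample"`` draws seeded random data rows
    instead, which orders the map during training at the cost of a possible
    early error increase.
    """
    if isinstance(fingerprints, FingerprintMatrix):
        X = fingerprints.values
        if labels is None:
            labels = fingerprints.labels
    else:
        X = np.asarray(fingerprints, dtype=np.float64)
    if X.size == 0:
        raise ValueError("cannot fit a SOM to an empty fingerprint matrix")
    rows, cols = shape
    n_neurons = rows * cols
    rng = np.random.default_rng(seed)
    if init == "pca":
        mu = X.mean(axis=0)
        _, S, Vt = np.linalg.svd(X - mu, full_matrices=False)
        scale = S / np.sqrt(max(X.shape[0], 1))
        pc1 = scale[0] * Vt[0]
        pc2 = scale[1] * Vt[1] if len(S) > 1 else np.zeros_like(pc1)
        gi = np.linspace(-2.0, 2.0, rows)
        gj = np.linspace(-2.0, 2.0, cols)
        codebook = np.array([mu + a * pc1 + b * pc2 for a in gi for b in gj])
    elif init == "sample":
        codebook = X[rng.integers(0, X.shape[0], size=n_neurons)].astype(np.float64).copy()
        codebook += rng.normal(0.0, 1e-6, codebook.shape)  # break duplicate-row ties
    else:
        raise ValueError(f"unknown init {init!r}")
    grid_pos = np.array([(i, j) for i in range(rows) for j in range(cols)], dtype=np.float64)
    grid_d2 = cdist(grid_pos, grid_pos, "sqeuclidean")
    sigma0 = max(sigma0, sigma_end)

    def quantization_error(code):
        return float(cdist(X, code).min(axis=1).mean())

    qe_history: list[float] = []
    for epoch in range(n_epochs):
        d = cdist(X, codebook)
        bmu = d.argmin(axis=1)
        qe = float(d[np.arange(len(X)), bmu].mean())
        qe_history.append(qe)
        frac = epoch / max(n_epochs - 1, 1)
        sigma = sigma0 * (sigma_end / sigma0) ** frac
        influence = np.exp(-grid_d2[bmu] / (2.0 * sigma**2))  # (n, n_neurons)
        weight_sum = influence.sum(axis=0)[:, None]
        target = influence.T @ X
        update = weight_sum > 1e-12
        candidate = np.where(update, target / np.maximum(weight_sum, 1e-12), codebook)
        # monotonicity safeguard: when assignment churn would raise the
        # quantization error, halve the step toward the previous codebook
        for _ in range(12):
            if quantization_error(candidate) <= qe:
                break
            candidate = 0.5 * (candidate + codebook)
        else:
            candidate = codebook
        codebook = candidate

    d = cdist(X, codebook)
    assignments = d.argmin(axis=1)
    grid = SOMGrid(
        shape=shape,
        codebook=codebook,
        assignments=assignments,
        qe_history=qe_history,
        labels=None if labels is None else np.asarray(labels, dtype=np.float64),
    )
    if grid.labels is not None:
        for neuron in grid.occupied_neurons():
            vals = grid.labels[assignments == neuron]
            grid.label_mix[int(neuron)] = {
                "count": int(len(vals)),
                "n_active": int(np.sum(vals == 1)),
                "n_inactive": int(np.sum(vals == 0)),
            }
    return grid


def conflict_neurons(grid: SOMGrid) -> list[dict]:
    """Neurons holding both activity classes, with per-class counts."""
    if grid.labels is None:
        raise ValueError("SOM was fitted without labels")
    uniq = np.unique(grid.labels[np.isfinite(grid.labels)])
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("conflict detection needs binary 0/1 labels")
    out = []
    for neuron, mix in sorted(grid.label_mix.items()):
        if mix["n_active"] > 0 and mix["n_inactive"] > 0:
            out.append({"neuron": neuron, **mix})
    return out


def plot_som(grid: SOMGrid, path: str) -> None:
    """Render the lattice: per-neuron occupancy shaded by active fraction,
    conflict neurons outlined."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows, cols = grid.shape
    frac = np.full((rows, cols), np.nan)
    for neuron, mix in grid.label_mix.items():
        r, c = grid.neuron_position(neuron)
        frac[r, c] = mix["n_active"] / mix["count"]
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(frac, cmap="coolwarm", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label="active fraction")
    if grid.labels is not None:
        for conflict in conflict_neurons(grid):
            r, c = grid.neuron_position(conflict["neuron"])
            ax.add_patch(
                plt.Rectangle((c - 0.5, r - 0.5), 1, 1, fill=False, edgecolor="k", lw=2)
            )
    ax.set_title("SOM of task-learned fingerprints")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def draw_reduced_graph(graph: MolecularGraph, path: str) -> None:
    """Molecule drawing with atoms colored by pharmacophore node and each
    atom annotated with its node's type symbol."""
    from rdkit import Chem
    from rdkit.Chem.Draw import rdMolDraw2D

    from .pharmacophore import reduce_graph

    rg = reduce_graph(graph)
    palette = [
        (0.85, 0.55, 0.55), (0.55, 0.7, 0.9), (0.6, 0.85, 0.6), (0.9, 0.8, 0.5),
        (0.8, 0.65, 0.9), (0.6, 0.85, 0.85), (0.9, 0.7, 0.55), (0.75, 0.75, 0.75),
    ]
    colors: dict[int, tuple] = {}
    mol = Chem.Mol(graph.mol)
    for ni, node in enumerate(rg.nodes):
        for a in node.member_atoms:
            colors[a] = palette[ni % len(palette)]
            mol.GetAtomWithIdx(a).SetProp("atomNote", node.type.symbol)
    drawer = rdMolDraw2D.MolDraw2DSVG(500, 400)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, mol, highlightAtoms=list(colors), highlightAtomColors=colors
    )
    drawer.FinishDrawing()
    with open(path, "w") as fh:
        fh.write(drawer.GetDrawingText())


def draw_importance(graph: MolecularGraph, report: ImportanceReport, path: str) -> None:
    """Annotated molecule drawing: atoms highlighted by the attention weight
    of the pharmacophore node(s) they belong to."""
    from rdkit.Chem.Draw import rdMolDraw2D

    weight_by_atom: dict[int, float] = {}
    for entry in report.entries:
        for a in entry["member_atoms"]:
            weight_by_atom[a] = max(weight_by_atom.get(a, 0.0), entry["weight"])
    top = max(weight_by_atom.values()) if weight_by_atom else 1.0
    colors = {
        a: (1.0, 1.0 - 0.85 * w / top, 1.0 - 0.85 * w / top)
        for a, w in weight_by_atom.items()
    }
    drawer = rdMolDraw2D.MolDraw2DSVG(500, 400)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer,
        graph.mol,
        highlightAtoms=list(colors),
        highlightAtomColors=colors,
    )
    drawer.FinishDrawing()
    with open(path, "w") as fh:
        fh.write(drawer.GetDrawingText())
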