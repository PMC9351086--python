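"""The four-phase reduced-graph message-passing network.

A molecule flows through four phases:

1. **Atom-level message passing** (K rounds).  Messages are gathered over
   bonded neighbours with single-head attention (a learned compatibility score
   of center and neighbour states, leaky-rectified then softmax-normalized);
   bond features are folded into each neighbour's score and value terms, so
   the first round sees a linear map of the concatenated neighbour-atom and
   bond features.  The update producing ``h^j`` adds the message to ``j - 1``
   skip-connection residuals — linear maps of the earlier hidden states
   ``h^1 .. h^{j-1}`` — before the nonlinearity.
2. **Graph reducing.**  Atoms pool into pharmacophore nodes: the sum of member
   hidden states is the node's initial state ``S_rg``; an attention gather
   over the members produces a message; a GRU blends the two.
3. **RG-level message passing** (T rounds) over the reduced graph, with the
   integer edge weight embedded and injected like a bond feature.  A molecule
   reduced to a single pharmacophore node skips this phase (flagged).
4. **Molecule readout** — graph reducing's special case where all nodes belong
   to one group: ``S_mol`` is the node-state sum, attention over the nodes
   gives the readout weights (the per-pharmacophore importances), and a GRU
   produces the molecule embedding ``h_mol``, the task-learned fingerprint.

An MLP head maps ``h_mol`` to the prediction: one value per task for
regression, a two-score column pair per task for classification.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .molio import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, MolecularGraph, featurize
from .pharmacophore import ReducedGraph, reduce_graph


class SinglePharmacophoreError(ValueError):
    """Raised in strict mode for molecules that reduce to one node."""


@dataclass
class ModelConfig:
    hidden_dim: int = 128          # also the fingerprint dimension
    n_atom_steps: int = 3          # K, atom-level rounds
    n_rg_steps: int = 2            # T, RG-level rounds
    dropout: float = 0.1
    n_tasks: int = 1
    task_type: str = "regression"  # "regression" | "classification"
    seed: int = 0
    leaky_slope: float = 0.2
    attention_heads: int = 1       # single-head; kept explicit in the config
    gru_carries_initial_state: bool = True  # carried state = S, input = message
    dropout_at_rg_level: bool = True
    max_edge_weight: int = 4       # RG edge weights clip here for the embedding
    strict_single_pharmacophore: bool = False

    def __post_init__(self):
        if self.hidden_dim <= 0:
            raise ValueError("hidden_dim must be positive")
        if self.task_type not in ("regression", "classification"):
            raise ValueError(f"unknown task_type {self.task_type!r}")
        if self.attention_heads != 1:
            raise ValueError("only single-head attention is implemented")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 2 <= self.n_atom_steps <= 5:
            warnings.warn(
                f"n_atom_steps={self.n_atom_steps} outside the searched range [2, 5]",
                stacklevel=2,
            )
        if not 1 <= self.n_rg_steps <= 3:
            warnings.warn(
                f"n_rg_steps={self.n_rg_steps} outside the searched range [1, 3]",
                stacklevel=2,
            )

    @property
    def output_dim(self) -> int:
        return self.n_tasks if self.task_type == "regression" else 2 * self.n_tasks


@dataclass
class PreparedMolecule:
    """Featurized + reduced arrays for one molecule, ready for batching."""

    graph: MolecularGraph
    rg: ReducedGraph
    X: np.ndarray                 # (n_atoms, d_atom)
    edge_src: np.ndarray          # directed bonds, both orientations
    edge_dst: np.ndarray
    edge_feat: np.ndarray         # (n_directed, d_bond)
    member_node: np.ndarray       # membership pairs: node index per pair
    member_atom: np.ndarray       # membership pairs: atom index per pair
    rg_src: np.ndarray            # directed RG edges
    rg_dst: np.ndarray
    rg_weight: np.ndarray         # integer weights, aligned with rg_src


def prepare_molecule(graph: MolecularGraph) -> PreparedMolecule:
    X, E = featurize(graph)
    rg = reduce_graph(graph)
    src, dst, feats = [], [], []
    for k, (a, b, _) in enumerate(graph.bonds):
        src += [a, b]
        dst += [b, a]
        feats += [E[k], E[k]]
    member_node, member_atom = [], []
    for ni, node in enumerate(rg.nodes):
        for a in sorted(node.member_atoms):
            member_node.append(ni)
            member_atom.append(a)
    rsrc, rdst, rw = [], [], []
    for i, j, w in rg.edges:
        rsrc += [i, j]
        rdst += [j, i]
        rw += [w, w]
    return PreparedMolecule(
        graph=graph,
        rg=rg,
        X=X,
        edge_src=np.asarray(src, dtype=np.intp),
        edge_dst=np.asarray(dst, dtype=np.intp),
        edge_feat=np.asarray(feats, dtype=np.float64).reshape(len(src), BOND_FEATURE_DIM),
        member_node=np.asarray(member_node, dtype=np.intp),
        member_atom=np.asarray(member_atom, dtype=np.intp),
        rg_src=np.asarray(rsrc, dtype=np.intp),
        rg_dst=np.asarray(rdst, dtype=np.intp),
        rg_weight=np.asarray(rw, dtype=np.intp),
    )


@dataclass
class GraphBatch:
    """A disjoint union of prepared molecules with global indices."""

    X: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_feat: np.ndarray
    member_node: np.ndarray
    member_atom: np.ndarray
    rg_src: np.ndarray
    rg_dst: np.ndarray
    rg_weight: np.ndarray
    node_mol: np.ndarray          # molecule id per pharmacophore node
    n_atoms: int
    n_nodes: int
    n_mols: int
    node_has_rg_edge: np.ndarray  # (n_nodes, 1) float mask
    single_flags: np.ndarray      # (n_mols,) bool
    mols: list[PreparedMolecule]
    node_offsets: np.ndarray      # first global node index of each molecule


def make_batch(prepared: Sequence[PreparedMolecule]) -> GraphBatch:
    Xs, esrc, edst, efeat = [], [], [], []
    mnode, matom, rsrc, rdst, rw, node_mol = [], [], [], [], [], []
    atom_off = node_off = 0
    node_offsets = []
    single = []
    for mi, pm in enumerate(prepared):
        n_atoms, n_nodes = pm.X.shape[0], pm.rg.n_nodes
        Xs.append(pm.X)
        esrc.append(pm.edge_src + atom_off)
        edst.append(pm.edge_dst + atom_off)
        efeat.append(pm.edge_feat)
        mnode.append(pm.member_node + node_off)
        matom.append(pm.member_atom + atom_off)
        rsrc.append(pm.rg_src + node_off)
        rdst.append(pm.rg_dst + node_off)
        rw.append(pm.rg_weight)
        node_mol.append(np.full(n_nodes, mi, dtype=np.intp))
        node_offsets.append(node_off)
        single.append(pm.rg.single_pharmacophore)
        atom_off += n_atoms
        node_off += n_nodes
    cat = lambda xs, d=np.intp: (
        np.concatenate(xs) if xs and sum(len(x) for x in xs) else np.zeros(0, dtype=d)
    )
    rdst_all = cat(rdst)
    has_edge = np.zeros((node_off, 1))
    if rdst_all.size:
        has_edge[np.unique(rdst_all), 0] = 1.0
    return GraphBatch(
        X=np.concatenate(Xs),
        edge_src=cat(esrc),
        edge_dst=cat(edst),
        edge_feat=(
            np.concatenate(efeat)
            if sum(e.shape[0] for e in efeat)
            else np.zeros((0, BOND_FEATURE_DIM))
        ),
        member_node=cat(mnode),
        member_atom=cat(matom),
        rg_src=cat(rsrc),
        rg_dst=rdst_all,
        rg_weight=cat(rw),
        node_mol=cat(node_mol),
        n_atoms=atom_off,
        n_nodes=node_off,
        n_mols=len(prepared),
        node_has_rg_edge=has_edge,
        single_flags=np.asarray(single, dtype=bool),
        mols=list(prepared),
        node_offsets=np.asarray(node_offsets, dtype=np.intp),
    )


@dataclass
class ForwardResult:
    y: Tensor                      # (n_mols, output_dim)
    h_mol: Tensor                  # (n_mols, hidden_dim)
    readout_weights: np.ndarray    # (n_nodes,) attention per pharmacophore node
    membership_weights: np.ndarray # (n_membership_pairs,)
    rg_attention: list[np.ndarray] # per RG step, (n_directed_rg_edges,)
    atom_attention: list[np.ndarray]
    residual_counts: list[int]     # residual terms used at atom step j
    skip_flags: np.ndarray         # per molecule: RG phase skipped
    batch: GraphBatch


@dataclass
class Prediction:
    """Per-molecule output: prediction, fingerprint and attention report."""

    y_hat: np.ndarray              # (n_tasks,) regression / (n_tasks, 2) scores
    fingerprint: np.ndarray        # (hidden_dim,)
    attention_report: list[dict]   # per node: symbol, member atoms, weight
    single_pharmacophore: bool

    @property
    def probabilities(self) -> np.ndarray:
        """Classification scores as per-task positive-class probabilities."""
        if self.y_hat.ndim != 2:
            raise ValueError("probabilities are defined for classification output")
        z = self.y_hat - self.y_hat.max(axis=1, keepdims=True)
        e = np.exp(z)
        return (e[:, 1] / e.sum(axis=1))


class RGMPNN:
    """Reduced-graph message-passing network over batched molecular graphs."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self.y_mean: float = 0.0   # regression label standardization (set by trainer)
        self.y_std: float = 1.0
        self._rng = np.random.default_rng(config.seed)
        self._build()

    # -- parameter construction -------------------------------------------
    def _glorot(self, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return self._rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))

    def _add(self, name: str, arr: np.ndarray) -> None:
        self.params[name] = ad.parameter(arr)

    def _add_attention(self, prefix: str, extra_dim: int = 0) -> None:
        h = self.config.hidden_dim
        self._add(f"{prefix}_Watt", self._glorot(h, h))
        self._add(f"{prefix}_ac", self._glorot(h, 1))
        self._add(f"{prefix}_an", self._glorot(h, 1))
        self._add(f"{prefix}_Wval", self._glorot(h, h))
        if extra_dim:
            self._add(f"{prefix}_ws", self._glorot(extra_dim, 1))
            self._add(f"{prefix}_Wv", self._glorot(extra_dim, h))

    def _add_gru(self, prefix: str) -> None:
        h = self.config.hidden_dim
        for gate in ("z", "r", "n"):
            self._add(f"{prefix}_W{gate}", self._glorot(h, h))
            self._add(f"{prefix}_U{gate}", self._glorot(h, h))
            self._add(f"{prefix}_b{gate}", np.zeros((1, h)))

    def _build(self) -> None:
        cfg = self.config
        h = cfg.hidden_dim
        self._add("W_in", self._glorot(ATOM_FEATURE_DIM, h))
        self._add("b_in", np.zeros((1, h)))
        for j in range(1, cfg.n_atom_steps + 1):
            self._add_attention(f"atom{j}", extra_dim=BOND_FEATURE_DIM)
            for i in range(1, j):
                self._add(f"atom{j}_Wres{i}", self._glorot(h, h))
        self._add_attention("red")
        self._add_gru("red")
        for t in range(1, cfg.n_rg_steps + 1):
            self._add_attention(f"rg{t}", extra_dim=h)
            self._add(f"rg{t}_Wemb", self._glorot(cfg.max_edge_weight, h))
        self._add_gru("rg")
        self._add_attention("ro")
        self._add_gru("ro")
        self._add("mlp_W1", self._glorot(h, h))
        self._add("mlp_b1", np.zeros((1, h)))
        self._add("mlp_W2", self._glorot(h, cfg.output_dim))
        self._add("mlp_b2", np.zeros((1, cfg.output_dim)))

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def parameter_items(self) -> list[tuple[str, Tensor]]:
        return list(self.params.items())

    # -- building blocks ---------------------------------------------------
    def _attention_gather(
        self,
        prefix: str,
        center: Tensor,
        members: Tensor,
        seg: np.ndarray,
        src: np.ndarray,
        n_segments: int,
        extra: Tensor | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Weighted message for each center over its gather set.

        Weights are normalized exponentials of a leaky-rectified compatibility
        score of (center, member) pairs; the message is the weight-averaged
        linear map of member states.  Centers with an empty gather set receive
        a zero message.
        """
        p = self.params
        pc = center @ p[f"{prefix}_Watt"]
        pm = pc if members is center else members @ p[f"{prefix}_Watt"]
        q = pc @ p[f"{prefix}_ac"]
        k = pm @ p[f"{prefix}_an"]
        score = ad.gather_rows(q, seg) + ad.gather_rows(k, src)
        v = members @ p[f"{prefix}_Wval"]
        vg = ad.gather_rows(v, src)
        if extra is not None:
            score = score + extra @ p[f"{prefix}_ws"]
            vg = vg + extra @ p[f"{prefix}_Wv"]
        score = ad.leaky_relu(score, self.config.leaky_slope)
        weights = ad.segment_softmax(score, seg, n_segments)
        message = ad.segment_sum(weights * vg, seg, n_segments)
        return message, weights

    def _gru(self, prefix: str, carried: Tensor, message: Tensor) -> Tensor:
        if not self.config.gru_carries_initial_state:
            carried, message = message, carried
        p = self.params
        x, hp = message, carried
        z = ad.sigmoid(x @ p[f"{prefix}_Wz"] + hp @ p[f"{prefix}_Uz"] + p[f"{prefix}_bz"])
        r = ad.sigmoid(x @ p[f"{prefix}_Wr"] + hp @ p[f"{prefix}_Ur"] + p[f"{prefix}_br"])
        n = ad.tanh(x @ p[f"{prefix}_Wn"] + r * (hp @ p[f"{prefix}_Un"]) + p[f"{prefix}_bn"])
        return (1.0 - z) * n + z * hp

    # -- forward pass ------------------------------------------------------
    def forward(
        self,
        batch: GraphBatch,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> ForwardResult:
        cfg = self.config
        if cfg.strict_single_pharmacophore and batch.single_flags.any():
            bad = [batch.mols[i].graph.canonical_smiles for i in np.flatnonzero(batch.single_flags)]
            raise SinglePharmacophoreError(f"single-pharmacophore molecules rejected: {bad}")
        p = self.params
        drop = cfg.dropout if training else 0.0
        if drop > 0 and rng is None:
            rng = np.random.default_rng(cfg.seed)

        # phase 1: atom-level message passing with k-1 residuals
        X = ad.constant(batch.X)
        Ef = ad.constant(batch.edge_feat)
        hs = [X @ p["W_in"] + p["b_in"]]  # hs[j] = h^j
        atom_attention: list[np.ndarray] = []
        residual_counts: list[int] = []
        for j in range(1, cfg.n_atom_steps + 1):
            message, w = self._attention_gather(
                f"atom{j}", hs[-1], hs[-1], batch.edge_dst, batch.edge_src,
                batch.n_atoms, extra=Ef,
            )
            pre = message
            n_res = 0
            for i in range(1, j):
                pre = pre + hs[i] @ p[f"atom{j}_Wres{i}"]
                n_res += 1
            residual_counts.append(n_res)
            hj = ad.relu(pre)
            if drop > 0:
                hj = ad.dropout(hj, drop, rng)
            hs.append(hj)
            atom_attention.append(w.data[:, 0].copy())

        # phase 2: graph reducing — sum-initialized pooling + GRU
        h_atoms = hs[-1]
        members = ad.gather_rows(h_atoms, batch.member_atom)
        s_rg = ad.segment_sum(members, batch.member_node, batch.n_nodes)
        message, w_mem = self._attention_gather(
            "red", s_rg, h_atoms, batch.member_node, batch.member_atom, batch.n_nodes
        )
        h_rg = self._gru("red", s_rg, message)

        # phase 3: RG-level message passing (skipped for single-node RGs)
        keep = ad.constant(batch.node_has_rg_edge)
        rg_attention: list[np.ndarray] = []
        for t in range(1, cfg.n_rg_steps + 1):
            if batch.rg_src.size:
                emb = ad.gather_rows(
                    p[f"rg{t}_Wemb"],
                    np.clip(batch.rg_weight, 1, cfg.max_edge_weight) - 1,
                )
                message, w_rg = self._attention_gather(
                    f"rg{t}", h_rg, h_rg, batch.rg_dst, batch.rg_src,
                    batch.n_nodes, extra=emb,
                )
                h_new = self._gru("rg", h_rg, message)
                if drop > 0 and cfg.dropout_at_rg_level:
                    h_new = ad.dropout(h_new, drop, rng)
                h_rg = keep * h_new + (1.0 - keep) * h_rg
                rg_attention.append(w_rg.data[:, 0].copy())
            else:
                rg_attention.append(np.zeros(0))

        # phase 4: molecule readout — reducing with one all-member group
        s_mol = ad.segment_sum(h_rg, batch.node_mol, batch.n_mols)
        message, w_ro = self._attention_gather(
            "ro", s_mol, h_rg, batch.node_mol,
            np.arange(batch.n_nodes, dtype=np.intp), batch.n_mols,
        )
        h_mol = self._gru("ro", s_mol, message)

        hidden = ad.relu(h_mol @ p["mlp_W1"] + p["mlp_b1"])
        if drop > 0:
            hidden = ad.dropout(hidden, drop, rng)
        y = hidden @ p["mlp_W2"] + p["mlp_b2"]
        return ForwardResult(
            y=y,
            h_mol=h_mol,
            readout_weights=w_ro.data[:, 0].copy(),
            membership_weights=w_mem.data[:, 0].copy(),
            rg_attention=rg_attention,
            atom_attention=atom_attention,
            residual_counts=residual_counts,
            skip_flags=batch.single_flags.copy(),
            batch=batch,
        )

    # -- inference API -----------------------------------------------------
    def predict(
        self, graphs: Sequence[MolecularGraph] | Sequence[PreparedMolecule]
    ) -> list[Prediction]:
        prepared = [
            g if isinstance(g, PreparedMolecule) else prepare_molecule(g) for g in graphs
        ]
        if not prepared:
            return []
        batch = make_batch(prepared)
        result = self.forward(batch, training=False)
        return self.predictions_from(result)

    def predictions_from(self, result: ForwardResult) -> list[Prediction]:
        batch = result.batch
        y = result.y.data
        out: list[Prediction] = []
        for mi, pm in enumerate(batch.mols):
            if self.config.task_type == "regression":
                y_hat = y[mi] * self.y_std + self.y_mean
            else:
                y_hat = y[mi].reshape(self.config.n_tasks, 2)
            node_idx = np.flatnonzero(batch.node_mol == mi)
            report = sorted(
                (
                    {
                        "symbol": pm.rg.nodes[ni - batch.node_offsets[mi]].type.symbol,
                        "ring": pm.rg.nodes[ni - batch.node_offsets[mi]].type.ring.name,
                        "feature": pm.rg.nodes[ni - batch.node_offsets[mi]].type.feature.name,
                        "member_atoms": sorted(
                            pm.rg.nodes[ni - batch.node_offsets[mi]].member_atoms
                        ),
                        "weight": float(result.readout_weights[ni]),
                    }
                    for ni in node_idx
                ),
                key=lambda d: -d["weight"],
            )
            out.append(
                Prediction(
                    y_hat=y_hat,
                    fingerprint=result.h_mol.data[mi].copy(),
                    attention_report=report,
                    single_pharmacophore=bool(batch.single_flags[mi]),
                )
            )
        return out

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.array(state[k], dtype=np.float64)

    def save(self, path: str) -> None:
        """Write config (JSON sidecar) + weights (npz) under a path prefix."""
        meta = {"config": asdict(self.config), "y_mean": self.y_mean, "y_std": self.y_std,
                "format_version": 1}
        with open(f"{path}.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        np.savez(f"{path}.npz", **self.state_dict())

    @classmethod
    def load(cls, path: str) -> "RGMPNN":
        with open(f"{path}.json") as fh:
            meta = json.load(fh)
        model = cls(ModelConfig(**meta["config"]))
        with np.load(f"{path}.npz") as data:
            model.load_state_dict({k: data[k] for k in data.files})
        model.y_mean, model.y_std = meta["y_mean"], meta["y_std"]
        return model
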