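"""Dataset splitting, training loop, random hyperparameter search, metrics.

The evaluation protocol: datasets split 8:1:1 into train/validation/test,
either uniformly at random or by Bemis-Murcko scaffold (all molecules sharing
a scaffold land in the same partition).  Each experiment is repeated five
times with different seeds and reported as mean +/- standard error, where the
standard error is the standard deviation across runs divided by the square
root of five.  Regression is scored by RMSE; classification by ROC-AUC and
Matthews correlation (both robust to class imbalance).

Training uses Adam on mean-squared-error (regression, on labels standardized
with training-set statistics) or two-score cross-entropy per task
(classification), with early stopping on the validation metric.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from . import autodiff as ad
from .autodiff import Tensor
from .molio import ConfigurationError, LabeledDataset
from .network import GraphBatch, ModelConfig, PreparedMolecule, RGMPNN, make_batch, prepare_molecule

log = logging.getLogger(__name__)


class SplitError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    method: str = "random"  # "random" | "scaffold"
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    repeat_index: int = 1

    def __post_init__(self):
        if self.method not in ("random", "scaffold"):
            raise ConfigurationError(f"unknown split method {self.method!r}")
        if not math.isclose(sum(self.fractions), 1.0):
            raise ConfigurationError("split fractions must sum to 1")
        if not 1 <= self.repeat_index <= 5:
            raise ConfigurationError("repeat_index must be in 1..5")


def random_split(
    dataset: LabeledDataset, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniform 8:1:1 split; identical partitions for identical seeds."""
    n = len(dataset)
    if n < 10:
        raise SplitError(f"dataset of {n} molecules is too small to split 8:1:1")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(spec.fractions[0] * n)
    n_val = int(spec.fractions[1] * n)
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def murcko_scaffold(graph) -> str:
    """Bemis-Murcko scaffold SMILES; empty string for acyclic molecules."""
    return MurckoScaffold.MurckoScaffoldSmiles(mol=graph.mol)


def scaffold_split(
    dataset: LabeledDataset, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaffold-grouped 8:1:1 split.

    Molecules are grouped by Bemis-Murcko scaffold; whole groups are assigned
    (in seed-shuffled order) greedily to train, then validation, then test, so
    no scaffold ever appears in two partitions.
    """
    n = len(dataset)
    if n < 10:
        raise SplitError(f"dataset of {n} molecules is too small to split 8:1:1")
    groups: dict[str, list[int]] = {}
    for i, (graph, _) in enumerate(dataset.records):
        groups.setdefault(murcko_scaffold(graph), []).append(i)
    if max(len(v) for v in groups.values()) > 0.8 * n:
        warnings.warn(
            "one scaffold covers more than 80% of the data; "
            "validation/test partitions may be under-filled"
        )
    rng = np.random.default_rng(spec.seed)
    keys = list(groups)
    rng.shuffle(keys)
    train, val, test = [], [], []
    for key in keys:
        members = groups[key]
        if len(train) < spec.fractions[0] * n:
            train.extend(members)
        elif len(val) < spec.fractions[1] * n:
            val.extend(members)
        else:
            test.extend(members)
    return np.asarray(train), np.asarray(val), np.asarray(test)


def split_dataset(dataset: LabeledDataset, spec: SplitSpec):
    return (random_split if spec.method == "random" else scaffold_split)(dataset, spec)


# -- losses and metrics ----------------------------------------------------

def _masked_mse(y_pred: Tensor, y_true: np.ndarray) -> Tensor:
    mask = np.isfinite(y_true)
    target = np.where(mask, y_true, 0.0)
    diff = (y_pred - ad.constant(target)) * ad.constant(mask.astype(np.float64))
    return ad.total(ad.square(diff)) / float(max(mask.sum(), 1))


def _masked_cross_entropy(logits: Tensor, y_true: np.ndarray, n_tasks: int) -> Tensor:
    """Two-score-per-task cross-entropy with missing labels masked out."""
    mask = np.isfinite(y_true)
    y = np.where(mask, y_true, 0.0)
    n_present = max(int(mask.sum()), 1)
    loss = None
    for t in range(n_tasks):
        sel = np.zeros((logits.shape[1], 2))
        sel[2 * t, 0] = sel[2 * t + 1, 1] = 1.0
        pair = logits @ ad.constant(sel)  # (n, 2) score pair for task t
        shift = ad.constant(pair.data.max(axis=1, keepdims=True))
        log_z = ad.log(ad.exp(pair - shift) @ ad.constant(np.ones((2, 1)))) + shift
        onehot = np.stack([1.0 - y[:, t], y[:, t]], axis=1)
        ll = ad.total((pair - log_z) * ad.constant(onehot * mask[:, t : t + 1]))
        loss = ll if loss is None else loss + ll
    return -loss / float(n_present)


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true, y_pred = np.asarray(y_true, float).ravel(), np.asarray(y_pred, float).ravel()
    mask = np.isfinite(y_true)
    return float(np.sqrt(np.mean((y_true[mask] - y_pred[mask]) ** 2)))


def roc_auc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Mean per-task ROC-AUC with missing labels masked; NaN if undefined."""
    y_true = np.atleast_2d(np.asarray(y_true, float).T).T
    y_score = np.atleast_2d(np.asarray(y_score, float).T).T
    aucs = []
    for t in range(y_true.shape[1]):
        mask = np.isfinite(y_true[:, t])
        yt = y_true[mask, t]
        if len(np.unique(yt)) < 2:
            warnings.warn(f"task {t}: single-class partition, AUC undefined")
            continue
        aucs.append(roc_auc_score(yt, y_score[mask, t]))
    return float(np.mean(aucs)) if aucs else float("nan")


def mcc(y_true: np.ndarray, y_pred_binary: np.ndarray) -> float:
    """Mean per-task Matthews correlation with missing labels masked."""
    y_true = np.atleast_2d(np.asarray(y_true, float).T).T
    y_pred_binary = np.atleast_2d(np.asarray(y_pred_binary, float).T).T
    vals = []
    for t in range(y_true.shape[1]):
        mask = np.isfinite(y_true[:, t])
        if not mask.any():
            continue
        vals.append(matthews_corrcoef(y_true[mask, t], y_pred_binary[mask, t]))
    return float(np.mean(vals)) if vals else float("nan")


@dataclass
class MetricsReport:
    """Per-run metric values with the five-run standard-error convention."""

    metric: str
    runs: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.runs))

    @property
    def standard_error(self) -> float:
        """Standard deviation (ddof=1) over completed runs divided by sqrt(n)."""
        if len(self.runs) < 2:
            return float("nan")
        return float(np.std(self.runs, ddof=1) / np.sqrt(len(self.runs)))

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "runs": [float(r) for r in self.runs],
            "mean": self.mean,
            "standard_error": self.standard_error,
        }


# -- training --------------------------------------------------------------

@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4   # the searched "base" L2 penalty
    batch_size: int = 32
    max_epochs: int = 300
    patience: int = 30
    min_delta: float = 0.0

    def __post_init__(self):
        if self.patience <= 0:
            raise ConfigurationError("patience must be positive")


@dataclass
class TrainResult:
    model: RGMPNN
    history: list[dict]
    best_epoch: int
    best_val: float     # monitored value at the restored checkpoint (lower = better)
    best_metric: float  # reporting metric there (RMSE, or ROC-AUC for classification)
    stopped_early: bool


def _prepare_all(dataset: LabeledDataset) -> list[PreparedMolecule]:
    return [prepare_molecule(g) for g in dataset.graphs]


def _predict_scores(model: RGMPNN, batch: GraphBatch) -> np.ndarray:
    """Raw network output to score space: standardized mean for regression,
    positive-class probability per task for classification."""
    y = model.forward(batch, training=False).y.data
    if model.config.task_type == "regression":
        return y * model.y_std + model.y_mean
    n_tasks = model.config.n_tasks
    probs = np.empty((y.shape[0], n_tasks))
    for t in range(n_tasks):
        pair = y[:, 2 * t : 2 * t + 2]
        pair = pair - pair.max(axis=1, keepdims=True)
        e = np.exp(pair)
        probs[:, t] = e[:, 1] / e.sum(axis=1)
    return probs


def _validation_scores(model: RGMPNN, batch: GraphBatch, y: np.ndarray) -> dict[str, float]:
    """Validation monitor (smaller is better) and reporting metric.

    Regression monitors RMSE directly.  Classification monitors the masked
    cross-entropy of the validation set — ROC-AUC saturates as soon as the
    ranking is right, long before the readout has finished organizing, so
    loss is the quantity early stopping and checkpoint selection follow —
    while AUC is reported alongside.
    """
    scores = _predict_scores(model, batch)
    if model.config.task_type == "regression":
        value = rmse(y, scores)
        return {"monitor": value, "metric": value}
    p = np.clip(scores, 1e-12, 1.0 - 1e-12)
    mask = np.isfinite(y)
    yv = np.where(mask, y, 0.0)
    ll = (yv * np.log(p) + (1.0 - yv) * np.log(1.0 - p)) * mask
    loss = float(-ll.sum() / max(mask.sum(), 1))
    return {"monitor": loss, "metric": roc_auc(y, scores)}


def train(
    model: RGMPNN,
    dataset: LabeledDataset,
    train_idx: Sequence[int],
    val_idx: Sequence[int],
    config: TrainConfig | None = None,
    prepared: list[PreparedMolecule] | None = None,
) -> TrainResult:
    """Mini-batch Adam with early stopping on the validation metric.

    Returns the model restored to its best-validation checkpoint together
    with the per-epoch history.  All randomness (shuffling, dropout) derives
    from the model config's seed.
    """
    config = config or TrainConfig()
    if model.config.n_tasks != dataset.n_tasks:
        raise ConfigurationError(
            f"model has {model.config.n_tasks} tasks, dataset has {dataset.n_tasks}"
        )
    if model.config.task_type != dataset.task_type:
        raise ConfigurationError("model/dataset task_type mismatch")
    train_idx = np.asarray(train_idx, dtype=np.intp)
    val_idx = np.asarray(val_idx, dtype=np.intp)
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise SplitError("training and validation partitions must be non-empty")
    prepared = prepared if prepared is not None else _prepare_all(dataset)
    labels = dataset.labels

    if model.config.task_type == "regression":
        train_y = labels[train_idx]
        finite = train_y[np.isfinite(train_y)]
        model.y_mean = float(finite.mean())
        model.y_std = float(finite.std()) or 1.0

    rng = np.random.default_rng(model.config.seed)
    names = [k for k, _ in model.parameter_items()]
    decay_mask = [("_b" not in k and not k.startswith("b_")) for k in names]
    opt = ad.Adam(
        model.parameters(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
        decay_mask=decay_mask,
    )
    val_batch = make_batch([prepared[i] for i in val_idx])
    val_y = labels[val_idx]

    history: list[dict] = []
    best_val = None
    best_metric = float("nan")
    best_state = model.state_dict()
    best_epoch = 0
    stopped_early = False
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            chunk = train_idx[order[start : start + config.batch_size]]
            batch = make_batch([prepared[i] for i in chunk])
            y_true = labels[chunk]
            result = model.forward(batch, training=True, rng=rng)
            if model.config.task_type == "regression":
                target = (y_true - model.y_mean) / model.y_std
                loss = _masked_mse(result.y, target)
            else:
                loss = _masked_cross_entropy(result.y, y_true, model.config.n_tasks)
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch} "
                    f"(lr={config.learning_rate}, batch={config.batch_size})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val = _validation_scores(model, val_batch, val_y)
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_metric": val["metric"],
                "val_monitor": val["monitor"],
            }
        )
        if best_val is None or val["monitor"] < best_val - config.min_delta:
            best_val = val["monitor"]
            best_metric = val["metric"]
            best_state = model.state_dict()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            stopped_early = True
            break
    model.load_state_dict(best_state)
    return TrainResult(
        model=model,
        history=history,
        best_epoch=best_epoch,
        best_val=float(best_val),
        best_metric=float(best_metric),
        stopped_early=stopped_early,
    )


# -- random hyperparameter search ------------------------------------------

SEARCH_SPACE: dict[str, list] = {
    "weight_decay": [1e-3, 1e-4],
    "n_atom_steps": [2, 3, 4, 5],
    "n_rg_steps": [1, 2, 3],
    "batch_size": [16, 32],
    "hidden_dim": [64, 128, 256, 512],
    "dropout": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5],
}


def sample_config(rng: np.random.Generator) -> dict:
    """One uniform draw from every searched hyperparameter set."""
    return {k: v[rng.integers(len(v))] for k, v in SEARCH_SPACE.items()}


@dataclass
class SearchTrial:
    hyperparameters: dict
    val_monitor: float  # validation loss / RMSE at the trial's best epoch
    val_metric: float   # reporting metric there (ROC-AUC or RMSE)
    best_epoch: int


@dataclass
class SearchResult:
    best_model: RGMPNN
    best_hyperparameters: dict
    best_val: float     # monitored value of the winning trial
    best_metric: float = float("nan")
    trials: list[SearchTrial] = field(default_factory=list)


def hyperparameter_search(
    dataset: LabeledDataset,
    train_idx: Sequence[int],
    val_idx: Sequence[int],
    budget: int,
    seed: int = 0,
    trial_max_epochs: int = 20,
    trial_patience: int = 5,
    prepared: list[PreparedMolecule] | None = None,
) -> SearchResult:
    """Uniform random search; each trial trains with a short early-stop
    schedule and the best trial's trained model (by validation monitor) is
    returned."""
    if budget < 1:
        raise ConfigurationError("search budget must be >= 1")
    rng = np.random.default_rng(seed)
    prepared = prepared if prepared is not None else _prepare_all(dataset)
    result = SearchResult(best_model=None, best_hyperparameters=None, best_val=float("nan"))
    for trial_no in range(budget):
        hp = sample_config(rng)
        model = RGMPNN(
            ModelConfig(
                hidden_dim=hp["hidden_dim"],
                n_atom_steps=hp["n_atom_steps"],
                n_rg_steps=hp["n_rg_steps"],
                dropout=hp["dropout"],
                n_tasks=dataset.n_tasks,
                task_type=dataset.task_type,
                seed=int(rng.integers(2**31 - 1)),
            )
        )
        tc = TrainConfig(
            weight_decay=hp["weight_decay"],
            batch_size=hp["batch_size"],
            max_epochs=trial_max_epochs,
            patience=trial_patience,
        )
        tr = train(model, dataset, train_idx, val_idx, tc, prepared=prepared)
        result.trials.append(
            SearchTrial(
                hyperparameters=hp,
                val_monitor=tr.best_val,
                val_metric=tr.best_metric,
                best_epoch=tr.best_epoch,
            )
        )
        log.info(
            "trial %d/%d: %s -> val monitor %.4f, metric %.4f",
            trial_no + 1, budget, hp, tr.best_val, tr.best_metric,
        )
        if result.best_model is None or tr.best_val < result.best_val:
            result.best_model = tr.model
            result.best_hyperparameters = hp
            result.best_val = tr.best_val
            result.best_metric = tr.best_metric
    return result


def evaluate(
    model: RGMPNN,
    dataset: LabeledDataset,
    indices: Sequence[int],
    prepared: list[PreparedMolecule] | None = None,
) -> dict[str, float]:
    """Score a partition: RMSE for regression, ROC-AUC and MCC for
    classification (probability threshold 0.5 for the MCC class call)."""
    indices = np.asarray(indices, dtype=np.intp)
    prepared = prepared if prepared is not None else _prepare_all(dataset)
    batch = make_batch([prepared[i] for i in indices])
    y = dataset.labels[indices]
    scores = _predict_scores(model, batch)
    if model.config.task_type == "regression":
        return {"rmse": rmse(y, scores)}
    return {"roc_auc": roc_auc(y, scores), "mcc": mcc(y, (scores >= 0.5).astype(float))}


def repeated_evaluation(
    dataset: LabeledDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    split: SplitSpec,
    n_repeats: int = 5,
    prepared: list[PreparedMolecule] | None = None,
) -> dict[str, MetricsReport]:
    """Train/evaluate across seeded repeats and aggregate mean +/- SE."""
    prepared = prepared if prepared is not None else _prepare_all(dataset)
    runs: dict[str, list[float]] = {}
    for r in range(n_repeats):
        spec = replace(split, seed=split.seed + r, repeat_index=r + 1)
        tr_idx, va_idx, te_idx = split_dataset(dataset, spec)
        model = RGMPNN(replace(model_config, seed=model_config.seed + r))
        result = train(model, dataset, tr_idx, va_idx, train_config, prepared=prepared)
        for name, value in evaluate(result.model, dataset, te_idx, prepared=prepared).items():
            runs.setdefault(name, []).append(value)
    return {name: MetricsReport(metric=name, runs=vals) for name, vals in runs.items()}
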