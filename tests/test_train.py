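"""Splitting protocol, metric oracles, training loop and random search."""

import math

import numpy as np
import pytest

from pharmgnn.fixtures import FixtureSpec, default_regression_rule, generate_library, to_dataset
from pharmgnn.molio import ConfigurationError
from pharmgnn.network import ModelConfig, RGMPNN
from pharmgnn.train import (
    SEARCH_SPACE,
    MetricsReport,
    SplitSpec,
    TrainConfig,
    DivergenceError,
    SplitError,
    evaluate,
    hyperparameter_search,
    mcc,
    murcko_scaffold,
    random_split,
    rmse,
    roc_auc,
    sample_config,
    scaffold_split,
    train,
)

# -- splits ----------------------------------------------------------------

def test_random_split_sizes(classification200):
    tr, va, te = random_split(classification200, SplitSpec(seed=0))
    assert (len(tr), len(va), len(te)) == (160, 20, 20)


def test_random_split_seeded_identical(classification200):
    a = random_split(classification200, SplitSpec(seed=4))
    b = random_split(classification200, SplitSpec(seed=4))
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)
    c = random_split(classification200, SplitSpec(seed=5))
    assert not np.array_equal(a[0], c[0])


def test_random_split_disjoint_exhaustive(classification200):
    tr, va, te = random_split(classification200, SplitSpec(seed=1))
    allidx = np.concatenate([tr, va, te])
    assert len(allidx) == len(classification200)
    assert len(np.unique(allidx)) == len(allidx)


def test_split_rejects_tiny_dataset(classification200):
    with pytest.raises(SplitError):
        random_split(classification200.subset(range(5)), SplitSpec(seed=0))


def test_scaffold_split_exclusive_and_exhaustive(classification200):
    spec = SplitSpec(method="scaffold", seed=2)
    tr, va, te = scaffold_split(classification200, spec)
    allidx = np.concatenate([tr, va, te])
    assert len(np.unique(allidx)) == len(classification200)
    scaff = [murcko_scaffold(g) for g in classification200.graphs]
    part = {}
    for name, idx in (("tr", tr), ("va", va), ("te", te)):
        for i in idx:
            part.setdefault(scaff[i], set()).add(name)
    assert all(len(v) == 1 for v in part.values())


def test_shared_scaffold_copartitioned(classification200):
    tr, va, te = scaffold_split(classification200, SplitSpec(method="scaffold", seed=3))
    scaff = [murcko_scaffold(g) for g in classification200.graphs]
    target = scaff[0]
    twins = [i for i, s in enumerate(scaff) if s == target]
    for part in (tr, va, te):
        inside = set(part) & set(twins)
        assert inside in (set(), set(twins))


def test_acyclic_molecule_groups_under_empty_scaffold(tmp_path):
    from pharmgnn.molio import read_dataset, write_dataset

    smiles = ["CCO", "CCN", "CCC", "CCCC", "CCCl", "CCBr", "CC=O", "CCOC", "CCCO", "NCCN", "OCCO", "CCCN"]
    path = tmp_path / "acyclic.csv"
    write_dataset(path, smiles, np.zeros((len(smiles), 1)), ["label"])
    ds = read_dataset(path, task_type="regression")
    assert all(murcko_scaffold(g) == "" for g in ds.graphs)
    tr, va, te = scaffold_split(ds, SplitSpec(method="scaffold", seed=0))
    # a single (empty) scaffold group: everything lands in one partition
    assert len(tr) == len(ds) and len(va) == len(te) == 0


# -- metric oracles --------------------------------------------------------

def _pairwise_auc(y, s):
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _formula_mcc(tp, tn, fp, fn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom


@pytest.mark.parametrize("seed", range(5))
def test_auc_matches_pairwise_comparison_oracle(seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, 80).astype(float)
    y[:2] = [0, 1]  # both classes present
    s = np.round(rng.random(80), 2)  # ties included
    assert roc_auc(y, s) == pytest.approx(_pairwise_auc(y, s), abs=1e-10)


def test_mcc_matches_confusion_formula():
    """TP=40 TN=30 FP=10 FN=20 -> (40*30-10*20)/sqrt(50*60*50*40) = 0.408..."""
    y_true = np.array([1] * 40 + [0] * 30 + [0] * 10 + [1] * 20, dtype=float)
    y_pred = np.array([1] * 40 + [0] * 30 + [1] * 10 + [0] * 20, dtype=float)
    expected = _formula_mcc(40, 30, 10, 20)
    assert expected == pytest.approx(0.408, abs=5e-4)
    assert mcc(y_true, y_pred) == pytest.approx(expected, abs=1e-10)


@pytest.mark.parametrize("seed", range(3))
def test_rmse_matches_direct_formula(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
    assert rmse(a, b) == pytest.approx(np.sqrt(np.mean((a - b) ** 2)), abs=1e-12)


def test_perfect_predictions():
    y = np.array([0.0, 1, 1, 0, 1])
    assert rmse(y, y) == 0.0
    assert roc_auc(y, y) == 1.0
    assert mcc(y, y) == 1.0


def test_single_class_auc_missing_with_warning():
    with pytest.warns(UserWarning):
        value = roc_auc(np.ones(5), np.random.default_rng(0).random(5))
    assert math.isnan(value)


def test_metrics_report_standard_error_convention():
    report = MetricsReport(metric="roc_auc", runs=[0.9, 0.8, 0.85, 0.95, 0.7])
    assert report.standard_error == pytest.approx(
        np.std(report.runs, ddof=1) / np.sqrt(5), abs=1e-15
    )
    flat = MetricsReport(metric="roc_auc", runs=[0.9] * 5)
    assert flat.standard_error == 0.0


# -- training loop ---------------------------------------------------------

def test_training_overfits_small_regression(regression50):
    idx = np.arange(len(regression50))
    model = RGMPNN(ModelConfig(hidden_dim=32, n_atom_steps=3, n_rg_steps=2, dropout=0.0, seed=0))
    cfg = TrainConfig(weight_decay=0.0, batch_size=16, max_epochs=60, patience=60)
    result = train(model, regression50, idx, idx, cfg)
    assert result.history[-1]["train_loss"] < result.history[0]["train_loss"] / 5


def test_early_stopping_within_patience_of_best(regression50):
    idx = np.arange(len(regression50))
    model = RGMPNN(ModelConfig(hidden_dim=16, n_atom_steps=2, n_rg_steps=1, dropout=0.0, seed=1))
    cfg = TrainConfig(weight_decay=0.0, batch_size=16, max_epochs=200, patience=5)
    result = train(model, regression50, idx[:40], idx[40:], cfg)
    if result.stopped_early:
        assert result.history[-1]["epoch"] - result.best_epoch == 5


def test_fixed_seed_identical_loss_curve(regression50):
    idx = np.arange(len(regression50))
    curves = []
    for _ in range(2):
        model = RGMPNN(ModelConfig(hidden_dim=16, n_atom_steps=2, n_rg_steps=1, dropout=0.3, seed=9))
        cfg = TrainConfig(batch_size=16, max_epochs=5, patience=5)
        result = train(model, regression50, idx[:40], idx[40:], cfg)
        curves.append([h["train_loss"] for h in result.history])
    assert curves[0] == curves[1]


def test_task_count_mismatch_rejected(regression50):
    model = RGMPNN(ModelConfig(hidden_dim=8, n_atom_steps=2, n_rg_steps=1, seed=0, n_tasks=3))
    with pytest.raises(ConfigurationError):
        train(model, regression50, [0, 1], [2, 3], TrainConfig())


def test_divergent_loss_aborts(regression50):
    model = RGMPNN(ModelConfig(hidden_dim=8, n_atom_steps=2, n_rg_steps=1, dropout=0.0, seed=0))
    for p in model.parameters():
        p.data = p.data * np.inf
    with pytest.raises(DivergenceError):
        train(model, regression50, np.arange(40), np.arange(40, 50),
              TrainConfig(max_epochs=1))


# -- random search ---------------------------------------------------------

def test_sampled_configs_stay_inside_search_space():
    rng = np.random.default_rng(0)
    for _ in range(100):
        hp = sample_config(rng)
        for key, value in hp.items():
            assert value in SEARCH_SPACE[key]


def test_budget_one_returns_single_trial(regression50):
    res = hyperparameter_search(
        regression50, np.arange(40), np.arange(40, 50), budget=1, seed=3,
        trial_max_epochs=2, trial_patience=2,
    )
    assert len(res.trials) == 1
    assert res.best_hyperparameters == res.trials[0].hyperparameters


def test_seeded_search_identical_trial_sequence(regression50):
    seqs = []
    for _ in range(2):
        res = hyperparameter_search(
            regression50, np.arange(40), np.arange(40, 50), budget=3, seed=5,
            trial_max_epochs=1, trial_patience=1,
        )
        seqs.append([t.hyperparameters for t in res.trials])
    assert seqs[0] == seqs[1]


def test_five_repeat_sweep_reports_se_convention(regression50):
    """Five seeded repeats aggregate into mean +/- std(ddof=1)/sqrt(5)."""
    from pharmgnn.train import repeated_evaluation

    reports = repeated_evaluation(
        regression50,
        ModelConfig(hidden_dim=16, n_atom_steps=2, n_rg_steps=1, dropout=0.0, seed=0),
        TrainConfig(batch_size=16, max_epochs=2, patience=2),
        SplitSpec(seed=0),
        n_repeats=5,
    )
    report = reports["rmse"]
    assert len(report.runs) == 5
    assert report.standard_error == pytest.approx(
        np.std(report.runs, ddof=1) / np.sqrt(5), abs=1e-15
    )


def test_evaluate_regression_and_classification(regression50, classification200):
    m = RGMPNN(ModelConfig(hidden_dim=8, n_atom_steps=2, n_rg_steps=1, dropout=0.0, seed=0))
    out = evaluate(m, regression50, np.arange(10))
    assert set(out) == {"rmse"} and out["rmse"] >= 0
    mc = RGMPNN(ModelConfig(hidden_dim=8, n_atom_steps=2, n_rg_steps=1, dropout=0.0,
                            seed=0, task_type="classification"))
    out = evaluate(mc, classification200, np.arange(40))
    assert set(out) == {"roc_auc", "mcc"}
    assert -1 <= out["mcc"] <= 1 and 0 <= out["roc_auc"] <= 1
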