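import numpy as np
import pytest

from pharmgnn.fixtures import (
    ClassificationRule,
    FixtureSpec,
    default_library,
    default_regression_rule,
    generate_library,
    synth_labels,
    to_dataset,
)
from pharmgnn.molio import parse_molecule
from pharmgnn.network import ModelConfig, RGMPNN, make_batch, prepare_molecule


@pytest.fixture(scope="session")
def library200():
    """The packaged 200-molecule reference library (unlabeled records)."""
    return default_library(200, 7)


@pytest.fixture(scope="session")
def graphs200(library200):
    return [parse_molecule(r.smiles) for r in library200]


@pytest.fixture(scope="session")
def regression50():
    """50 molecules with a noiseless linear-in-type-counts label."""
    rule = default_regression_rule(seed=3, sigma=0.0)
    recs = generate_library(FixtureSpec(n_molecules=50, seed=11, label_rule=rule))
    return to_dataset(recs, "regression")


@pytest.fixture(scope="session")
def classification200():
    """200 molecules labeled by presence of an aromatic-donor node."""
    recs = generate_library(
        FixtureSpec(n_molecules=200, seed=21, label_rule=ClassificationRule())
    )
    return to_dataset(recs, "classification")


@pytest.fixture()
def tiny_model():
    return RGMPNN(
        ModelConfig(hidden_dim=16, n_atom_steps=3, n_rg_steps=2, dropout=0.0, seed=0)
    )


@pytest.fixture()
def small_batch(graphs200):
    return make_batch([prepare_molecule(g) for g in graphs200[:12]])
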