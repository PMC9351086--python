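"""Project task-learned fingerprints onto a self-organizing map.

Trains a small classifier, extracts the molecule embeddings (h_mol) of the
test molecules and fits an 8x8 SOM.  Molecules in the same neuron have
similar learned representations; neurons holding both actives and inactives
("conflict neurons") mark the decision boundary.
"""

import numpy as np

from pharmgnn import (
    ModelConfig, RGMPNN, SplitSpec, TrainConfig,
    conflict_neurons, extract_fingerprints, random_split, som_fit, train,
)
from pharmgnn.fixtures import ClassificationRule, FixtureSpec, generate_library, to_dataset

records = generate_library(
    FixtureSpec(n_molecules=400, seed=2, label_rule=ClassificationRule())
)
dataset = to_dataset(records, "classification")
train_idx, val_idx, test_idx = random_split(dataset, SplitSpec(seed=0))

model = RGMPNN(
    ModelConfig(hidden_dim=64, n_atom_steps=3, n_rg_steps=1, dropout=0.0,
                n_tasks=1, task_type="classification", seed=0)
)
train(model, dataset, train_idx, val_idx, TrainConfig(batch_size=32, max_epochs=15, patience=5))

test_graphs = [dataset.records[i][0] for i in test_idx]
test_labels = dataset.labels[test_idx, 0]
fps = extract_fingerprints(model, test_graphs, labels=test_labels)
grid = som_fit(fps, shape=(8, 8), n_epochs=100, seed=0)

print(f"fingerprints: {fps.values.shape[0]} molecules x {fps.values.shape[1]} dims")
print(f"quantization error: {grid.qe_history[0]:.3f} -> {grid.qe_history[-1]:.3f} "
      f"over {len(grid.qe_history)} epochs (non-increasing)")
print(f"occupied neurons: {len(grid.occupied_neurons())} of {grid.n_neurons}")
conflicts = conflict_neurons(grid)
print(f"conflict neurons (both classes): {len(conflicts)}")
for c in conflicts[:5]:
    print(f"  neuron {c['neuron']}: {c['n_active']} active / {c['n_inactive']} inactive")
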