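"""Architecture contracts of the four-phase network."""

import numpy as np
import pytest
from rdkit import Chem

import pharmgnn.autodiff as ad
from pharmgnn.molio import graph_from_mol, parse_molecule
from pharmgnn.network import (
    ModelConfig,
    RGMPNN,
    SinglePharmacophoreError,
    make_batch,
    prepare_molecule,
)


def _segment_sums(weights, seg, n):
    s = np.zeros(n)
    np.add.at(s, seg, weights)
    return s


def test_attention_weights_are_probability_vectors(tiny_model, small_batch):
    r = tiny_model.forward(small_batch)
    b = small_batch
    checks = [
        (r.readout_weights, b.node_mol, b.n_mols),
        (r.membership_weights, b.member_node, b.n_nodes),
    ]
    for w_step in r.atom_attention:
        checks.append((w_step, b.edge_dst, b.n_atoms))
    for w, seg, n in checks:
        assert w.min() >= 0
        sums = _segment_sums(w, seg, n)
        occupied = np.unique(seg)
        np.testing.assert_allclose(sums[occupied], 1.0, atol=1e-6)


@pytest.mark.parametrize("K", [2, 3, 5])
def test_residual_count_is_step_minus_one(K, graphs200):
    model = RGMPNN(ModelConfig(hidden_dim=8, n_atom_steps=K, n_rg_steps=1, dropout=0.0, seed=0))
    batch = make_batch([prepare_molecule(graphs200[0])])
    r = model.forward(batch)
    assert r.residual_counts == [j - 1 for j in range(1, K + 1)]


def test_forward_is_permutation_invariant(tiny_model, library200):
    rng = np.random.default_rng(1)
    for rec in library200[:10]:
        mol = Chem.MolFromSmiles(rec.smiles)
        perm = [int(x) for x in rng.permutation(mol.GetNumAtoms())]
        g1 = parse_molecule(rec.smiles)
        g2 = graph_from_mol(Chem.RenumberAtoms(mol, perm))
        p1 = tiny_model.predict([g1])[0]
        p2 = tiny_model.predict([g2])[0]
        np.testing.assert_allclose(p1.y_hat, p2.y_hat, rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(p1.fingerprint, p2.fingerprint, rtol=1e-5, atol=1e-8)


def test_two_smiles_spellings_identical_prediction(tiny_model):
    a = tiny_model.predict([parse_molecule("OC(=O)c1ccccc1")])[0]
    b = tiny_model.predict([parse_molecule("c1ccc(C(O)=O)cc1")])[0]
    np.testing.assert_allclose(a.y_hat, b.y_hat, rtol=1e-12)


def test_fixed_seed_bit_reproducible(graphs200):
    cfg = ModelConfig(hidden_dim=16, n_atom_steps=3, n_rg_steps=2, dropout=0.2, seed=42)
    batch = make_batch([prepare_molecule(g) for g in graphs200[:8]])
    outs = []
    for _ in range(2):
        model = RGMPNN(cfg)
        rng = np.random.default_rng(7)
        outs.append(model.forward(batch, training=True, rng=rng).y.data.copy())
    np.testing.assert_array_equal(outs[0], outs[1])


def test_batch_order_preserved(tiny_model, graphs200):
    singles = [tiny_model.predict([g])[0].y_hat for g in graphs200[:6]]
    batched = tiny_model.predict(graphs200[:6])
    for s, b in zip(singles, batched):
        np.testing.assert_allclose(s, b.y_hat, rtol=1e-9)


def test_single_pharmacophore_skips_rg_phase(tiny_model):
    p = tiny_model.predict([parse_molecule("CC")])[0]
    assert p.single_pharmacophore
    assert p.attention_report[0]["weight"] == 1.0


def test_single_node_state_untouched_by_rg_rounds():
    """RG-phase parameters must have no influence on a single-node molecule
    (the phase is skipped), while they do change a multi-node molecule."""
    single, multi = parse_molecule("c1ccccc1"), parse_molecule("Oc1ccccc1")
    m = RGMPNN(ModelConfig(hidden_dim=8, n_atom_steps=2, n_rg_steps=2, dropout=0.0, seed=3))
    fp_single = m.predict([single])[0].fingerprint
    fp_multi = m.predict([multi])[0].fingerprint
    rng = np.random.default_rng(0)
    for name, p in m.parameter_items():
        if name.startswith("rg"):
            p.data = rng.normal(0, 0.5, p.data.shape)
    np.testing.assert_allclose(m.predict([single])[0].fingerprint, fp_single, rtol=1e-12)
    assert np.abs(m.predict([multi])[0].fingerprint - fp_multi).max() > 1e-8


def test_strict_mode_rejects_single_pharmacophore():
    m = RGMPNN(
        ModelConfig(hidden_dim=8, n_atom_steps=2, n_rg_steps=1, dropout=0.0,
                    seed=0, strict_single_pharmacophore=True)
    )
    with pytest.raises(SinglePharmacophoreError):
        m.predict([parse_molecule("CC")])


def test_zero_initialized_maps_give_zero_embedding(tiny_model):
    """With every learned map zeroed and gates at neutral, the embedding
    collapses to the closed-form zero vector and the output to the bias."""
    tiny_model.load_state_dict(
        {k: np.zeros_like(v.data) for k, v in tiny_model.params.items()}
    )
    p = tiny_model.predict([parse_molecule("CC(=O)Nc1ccccc1")])[0]
    np.testing.assert_array_equal(p.fingerprint, 0.0)
    np.testing.assert_array_equal(p.y_hat, 0.0)


def test_fingerprint_length_equals_hidden_dim(graphs200):
    for h in (16, 32):
        m = RGMPNN(ModelConfig(hidden_dim=h, n_atom_steps=2, n_rg_steps=1, dropout=0.0, seed=0))
        assert m.predict([graphs200[0]])[0].fingerprint.shape == (h,)


def test_multitask_classification_output_shape(graphs200):
    m = RGMPNN(
        ModelConfig(hidden_dim=8, n_atom_steps=2, n_rg_steps=1, dropout=0.0,
                    seed=0, n_tasks=12, task_type="classification")
    )
    p = m.predict([graphs200[0]])[0]
    assert p.y_hat.shape == (12, 2)
    assert p.probabilities.shape == (12,)
    assert np.all((p.probabilities >= 0) & (p.probabilities <= 1))


def test_gradient_step_reduces_loss(tiny_model, small_batch):
    """One small-enough Adam step on a single batch strictly decreases MSE."""
    target = np.zeros((small_batch.n_mols, 1))

    def loss_value():
        r = tiny_model.forward(small_batch)
        return ad.total(ad.square(r.y - ad.constant(target))) / small_batch.n_mols

    before = float(loss_value().data)
    opt = ad.Adam(tiny_model.parameters(), lr=1e-3)
    loss = loss_value()
    opt.zero_grad()
    loss.backward()
    opt.step()
    after = float(loss_value().data)
    assert after < before


def test_out_of_range_steps_warn_but_run():
    with pytest.warns(UserWarning):
        ModelConfig(hidden_dim=8, n_atom_steps=6, n_rg_steps=1, seed=0)
    with pytest.warns(UserWarning):
        ModelConfig(hidden_dim=8, n_atom_steps=2, n_rg_steps=4, seed=0)


def test_checkpoint_roundtrip(tmp_path, tiny_model, graphs200):
    before = tiny_model.predict([graphs200[0]])[0]
    tiny_model.y_mean, tiny_model.y_std = 1.5, 2.0
    tiny_model.save(str(tmp_path / "ckpt"))
    loaded = RGMPNN.load(str(tmp_path / "ckpt"))
    after = loaded.predict([graphs200[0]])[0]
    # y_mean/y_std shift regression output; compare fingerprints and config
    np.testing.assert_array_equal(before.fingerprint, after.fingerprint)
    assert loaded.config == tiny_model.config
    assert loaded.y_mean == 1.5
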