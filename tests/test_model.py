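import copy

import numpy as np
import pytest

from ucnbench import GNNConfig, featurize, parse_molecule, train
from ucnbench.chem import MolecularGraph
from ucnbench.model import PackedBatch, TrainedGNN


def _permute_graph(graph: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    """Reindex atoms of a graph by perm (new index = position of old in perm)."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    return MolecularGraph(
        node_features=graph.node_features[perm],
        edge_index=inv[graph.edge_index],
        edge_features=graph.edge_features.copy(),
        smiles=graph.smiles,
    )


def test_forward_single_atom():
    model = TrainedGNN(GNNConfig(hidden_dim=8, head_hidden=8, seed=0))
    res = model.forward(featurize(parse_molecule("C")))
    assert res.node_embeddings.shape == (1, 8)
    assert np.isfinite(res.prediction)


def test_forward_benzene_symmetry(benzene_graph):
    model = TrainedGNN(GNNConfig(hidden_dim=8, head_hidden=8, seed=1))
    res = model.forward(benzene_graph)
    assert np.allclose(res.node_embeddings, res.node_embeddings[0])


def test_permutation_equivariance():
    """Prediction invariant, embeddings and UCN readout equivariant, 50 molecules."""
    from oracles import random_acyclic_molecule
    from rdkit import Chem

    model = TrainedGNN(GNNConfig(hidden_dim=8, head_hidden=8, seed=2))
    rng = np.random.default_rng(3)
    for _ in range(50):
        mol = parse_molecule(Chem.MolToSmiles(random_acyclic_molecule(rng, int(rng.integers(3, 10)))))
        graph = featurize(mol)
        perm = rng.permutation(mol.n_atoms)
        res = model.forward(graph)
        res_p = model.forward(_permute_graph(graph, perm))
        assert res_p.prediction == pytest.approx(res.prediction, abs=1e-9)
        assert np.allclose(res_p.node_embeddings, res.node_embeddings[perm], atol=1e-9)
        mask = sorted(rng.choice(mol.n_atoms, size=2, replace=False))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(perm.size)
        u = model.ucn_readout(res.node_embeddings, mask)
        u_p = model.ucn_readout(res_p.node_embeddings, [int(inv[v]) for v in mask])
        assert u_p == pytest.approx(u, abs=1e-9)


def test_ucn_readout_contracts(benzene_graph):
    model = TrainedGNN(GNNConfig(hidden_dim=8, head_hidden=8, seed=4))
    res = model.forward(benzene_graph)
    full = model.ucn_readout(res.node_embeddings, range(6))
    # benzene rows are identical, so any subset gives the same readout
    assert model.ucn_readout(res.node_embeddings, [2]) == pytest.approx(full, abs=1e-9)
    with pytest.raises(ValueError, match="empty atom set"):
        model.ucn_readout(res.node_embeddings, [])
    # zeroed xi head -> readout 0
    zeroed = TrainedGNN(GNNConfig(hidden_dim=8, head_hidden=8, seed=4))
    for k in ("V1", "c1", "v2", "c2"):
        zeroed.params[k] = np.zeros_like(zeroed.params[k])
    assert zeroed.ucn_readout(res.node_embeddings, [0, 1]) == 0.0


def test_predict_consistency_and_batching(trained_mse_model, small_split):
    model = trained_mse_model
    recs = sorted(
        {p.record_i.compound_id: p.record_i for p in small_split.test_pairs}.values(),
        key=lambda r: r.compound_id,
    )
    graphs = [featurize(r.molecule) for r in recs]
    singles = [model.predict(g) for g in graphs]
    assert singles[0] == pytest.approx(model.forward(graphs[0]).prediction)
    packed = model.forward_packed(PackedBatch(graphs))["yhat"]
    assert np.allclose(packed, singles, atol=1e-9)
    # inference needs no pair/mask information: works on an unseen molecule
    unseen = model.predict(featurize(parse_molecule("c1ccc2[nH]ccc2c1")))
    assert np.isfinite(unseen)


def test_dimension_mismatch_raises(trained_mse_model, benzene_graph):
    bad = MolecularGraph(
        node_features=benzene_graph.node_features[:, :5],
        edge_index=benzene_graph.edge_index,
        edge_features=benzene_graph.edge_features,
    )
    with pytest.raises(ValueError, match="feature dimension"):
        trained_mse_model.forward(bad)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _tiny_cfg(**kw):
    base = dict(
        hidden_dim=8, n_message_passes=2, head_hidden=8,
        learning_rate=3e-3, epochs=8, batch_pairs=8, seed=7,
    )
    base.update(kw)
    return GNNConfig(**base)


def test_train_determinism(small_split):
    m1 = train(small_split, _tiny_cfg())
    m2 = train(small_split, _tiny_cfg())
    for k in m1.params:
        assert np.array_equal(m1.params[k], m2.params[k])
    assert m1.training_log == m2.training_log


def test_lambda_zero_reduces_to_mse(small_split):
    mse = train(small_split, _tiny_cfg(loss_mode="mse"))
    ucn0 = train(small_split, _tiny_cfg(loss_mode="mse_ucn", lam=0.0))
    ac0 = train(small_split, _tiny_cfg(loss_mode="mse_ac", lam=0.0))
    assert mse.training_log == ucn0.training_log == ac0.training_log
    for k in mse.params:
        assert np.array_equal(mse.params[k], ucn0.params[k])
        assert np.array_equal(mse.params[k], ac0.params[k])


def test_training_loss_decreases(trained_mse_model, trained_ucn_model):
    for model in (trained_mse_model, trained_ucn_model):
        assert model.training_log[-1] <= 0.5 * model.training_log[0]


def test_zero_noise_fit_quality(small_split, trained_mse_model):
    """On the zero-noise series the MSE model fits train activities tightly."""
    recs = {
        r.compound_id: r
        for p in small_split.train_pairs
        for r in (p.record_i, p.record_j)
    }
    y = np.array([r.activity for r in recs.values()])
    yhat = np.array([trained_mse_model.predict(featurize(r.molecule)) for r in recs.values()])
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    assert rmse <= 0.1 * float(np.std(y))


def test_train_empty_errors(small_split):
    from ucnbench.pairing import BenchmarkSplit

    empty = BenchmarkSplit("t", [], [], frozenset(), frozenset())
    with pytest.raises(ValueError, match="empty training set"):
        train(empty, _tiny_cfg())


def test_config_validation():
    with pytest.raises(ValueError):
        GNNConfig(loss_mode="huber").validate()
    with pytest.raises(ValueError):
        GNNConfig(epochs=0).validate()
    with pytest.raises(ValueError):
        GNNConfig(learning_rate=-1).validate()


def test_gradient_check_total_loss(small_split):
    """Numeric vs analytic gradient of the combined loss on a 2-pair batch."""
    pairs = [p for p in small_split.train_pairs if p.evaluable][:2]
    model = TrainedGNN(_tiny_cfg(seed=13))
    graphs = []
    for p in pairs:
        graphs.append(featurize(p.record_i.molecule))
        graphs.append(featurize(p.record_j.molecule))
    batch = PackedBatch(graphs)
    ys = [(p.record_i.activity, p.record_j.activity) for p in pairs]
    masks = []
    for k, p in enumerate(pairs):
        masks.append(batch.offsets[2 * k] + np.asarray(sorted(p.uncommon_i)))
        masks.append(batch.offsets[2 * k + 1] + np.asarray(sorted(p.uncommon_j)))

    def loss_of(m):
        cache = m.forward_packed(batch)
        yh = cache["yhat"]
        L = 0.0
        for k, (yi, yj) in enumerate(ys):
            gi, gj = 2 * k, 2 * k + 1
            ui = m.ucn_readout_packed(cache, masks[gi])
            uj = m.ucn_readout_packed(cache, masks[gj])
            L += (yi - yh[gi]) ** 2 + (yj - yh[gj]) ** 2 + ((ui - uj) - (yi - yj)) ** 2
        return L / len(ys)

    from ucnbench.model import mask_operator

    cache = model.forward_packed(batch)
    yh = cache["yhat"]
    d_yhat = np.zeros(batch.n_graphs)
    du = np.zeros(len(masks))
    for k, (yi, yj) in enumerate(ys):
        gi, gj = 2 * k, 2 * k + 1
        d_yhat[gi] = 2 * (yh[gi] - yi) / len(ys)
        d_yhat[gj] = 2 * (yh[gj] - yj) / len(ys)
        ui = model.ucn_readout_packed(cache, masks[gi])
        uj = model.ucn_readout_packed(cache, masks[gj])
        e = (ui - uj) - (yi - yj)
        du[gi] = 2 * e / len(ys)
        du[gj] = -2 * e / len(ys)
    mask_op = mask_operator(masks, batch.n_nodes)
    grads, _ = model.backward_packed(batch, cache, d_yhat, (mask_op, du))

    rng = np.random.default_rng(0)
    eps = 1e-6
    for name in sorted(model.params):
        flat = np.atleast_1d(model.params[name]).ravel()
        for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss_of(model)
            flat[i] = orig - eps
            lm = loss_of(model)
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            ana = np.atleast_1d(grads[name]).ravel()[i]
            assert abs(num - ana) <= 1e-4 * max(1.0, abs(num), abs(ana)), name


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def test_checkpoint_roundtrip(tmp_path, trained_mse_model, benzene_graph):
    path = tmp_path / "model.json"
    trained_mse_model.save(path)
    loaded = TrainedGNN.load(path)
    assert loaded.predict(benzene_graph) == pytest.approx(
        trained_mse_model.predict(benzene_graph), abs=1e-12
    )
    assert loaded.training_log == trained_mse_model.training_log


def test_checkpoint_schema_mismatch(tmp_path, trained_mse_model):
    import json

    path = tmp_path / "model.json"
    trained_mse_model.save(path)
    blob = json.loads(path.read_text())
    blob["schema_hash"] = "deadbeef"
    path.write_text(json.dumps(blob))
    with pytest.raises(ValueError, match="schema hash mismatch"):
        TrainedGNN.load(path)
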