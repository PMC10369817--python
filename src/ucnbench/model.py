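"""Message-passing GNN regressor with an uncommon-node (UCN) readout head.

The network follows the standard message-passing scheme: node states are
initialised from atom features, then updated for ``n_message_passes`` rounds
using edge-conditioned linear messages (sum-aggregated over incoming edges)
followed by a perceptron update.  A scalar potency prediction is produced by a
two-layer head on the mean-pooled node embeddings.  A second, separate head
``xi`` with linear activations maps the mean embedding of a masked atom subset
to a scalar — the UCN readout used by the substructure-aware loss.

Everything, including backpropagation, is implemented in NumPy with explicit
forward caches and a reverse pass.  This keeps the model dependency-free,
deterministic under a seed, and gives attribution methods direct access to
gradients with respect to inputs and embeddings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

from .chem import EDGE_FEATURE_DIM, NODE_FEATURE_DIM, MolecularGraph, featurize
from .losses import MODES, PairLossInput, total_loss
from .pairing import BenchmarkSplit, CompoundPair

logger = logging.getLogger("ucnbench")


@dataclass
class GNNConfig:
    hidden_dim: int = 64
    n_message_passes: int = 3
    head_hidden: int = 64
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_pairs: int = 32
    seed: int = 0
    loss_mode: str = "mse"  # one of losses.MODES
    lam: float = 1.0  # weight of the auxiliary (AC or UCN) term
    activation: str = "relu"  # "relu" | "identity"; identity gives a linear model

    def validate(self) -> None:
        if self.loss_mode not in MODES:
            raise ValueError(f"loss_mode must be one of {MODES}")
        if self.activation not in ("relu", "identity"):
            raise ValueError("activation must be 'relu' or 'identity'")
        for name in ("hidden_dim", "n_message_passes", "head_hidden", "epochs", "batch_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class ForwardResult:
    node_embeddings: np.ndarray  # (N, hidden_dim), last message-passing layer
    prediction: float


# ---------------------------------------------------------------------------
# packed batches: many graphs in one set of arrays
# ---------------------------------------------------------------------------


class PackedBatch:
    """Block-diagonal packing of several molecular graphs."""

    def __init__(self, graphs: Sequence[MolecularGraph]):
        offsets = np.zeros(len(graphs), dtype=np.int64)
        total = 0
        xs, srcs, dsts, efs, gids = [], [], [], [], []
        for k, g in enumerate(graphs):
            offsets[k] = total
            xs.append(g.node_features)
            if g.edge_index.size:
                srcs.append(g.edge_index[0] + total)
                dsts.append(g.edge_index[1] + total)
                efs.append(g.edge_features)
            gids.append(np.full(g.n_atoms, k, dtype=np.int64))
            total += g.n_atoms
        self.n_graphs = len(graphs)
        self.n_nodes = total
        self.offsets = offsets
        self.X = np.concatenate(xs, axis=0) if xs else np.zeros((0, NODE_FEATURE_DIM))
        self.edge_src = np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.int64)
        self.edge_dst = np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.int64)
        self.EF = np.concatenate(efs, axis=0) if efs else np.zeros((0, EDGE_FEATURE_DIM))
        self.graph_id = np.concatenate(gids) if gids else np.zeros(0, dtype=np.int64)
        self.counts = np.bincount(self.graph_id, minlength=self.n_graphs).astype(np.float64)
        n_edges = self.edge_src.size
        # sparse incidence operators: scatter-to-destination, scatter-to-source,
        # and mean pooling (rows already carry 1/count weights)
        self.scatter_dst = sparse.csr_matrix(
            (np.ones(n_edges), (self.edge_dst, np.arange(n_edges))),
            shape=(self.n_nodes, n_edges),
        )
        self.scatter_src = sparse.csr_matrix(
            (np.ones(n_edges), (self.edge_src, np.arange(n_edges))),
            shape=(self.n_nodes, n_edges),
        )
        self.pool = sparse.csr_matrix(
            (1.0 / self.counts[self.graph_id], (self.graph_id, np.arange(self.n_nodes))),
            shape=(self.n_graphs, self.n_nodes),
        )

    def with_features(self, X: np.ndarray) -> "PackedBatch":
        """Same topology, different node features (used by integrated gradients)."""
        other = object.__new__(PackedBatch)
        other.__dict__ = dict(self.__dict__)
        other.X = X
        return other


def mask_operator(masks: Sequence[np.ndarray], n_nodes: int) -> sparse.csr_matrix:
    """Rows average the selected node rows: (n_masks x n_nodes), row sums 1."""
    rows = np.concatenate([np.full(m.size, k) for k, m in enumerate(masks)])
    cols = np.concatenate(masks)
    data = np.concatenate([np.full(m.size, 1.0 / m.size) for m in masks])
    return sparse.csr_matrix((data, (rows, cols)), shape=(len(masks), n_nodes))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class TrainedGNN:
    """Parameters + config; exposes forward, UCN readout and gradients."""

    def __init__(self, config: GNNConfig, params: Optional[Dict[str, np.ndarray]] = None):
        config.validate()
        self.config = config
        self.training_log: List[float] = []
        self.f_node = NODE_FEATURE_DIM
        self.f_edge = EDGE_FEATURE_DIM
        self.params = params if params is not None else self._init_params()

    # -- initialisation -----------------------------------------------------

    def _init_params(self) -> Dict[str, np.ndarray]:
        rng = np.random.default_rng(self.config.seed)
        d, H = self.config.hidden_dim, self.config.head_hidden

        def glorot(shape):
            scale = np.sqrt(2.0 / (shape[0] + shape[-1]))
            return rng.normal(0.0, scale, size=shape)

        p: Dict[str, np.ndarray] = {
            "W_in": glorot((self.f_node, d)),
            "b_in": np.zeros(d),
        }
        for t in range(self.config.n_message_passes):
            p[f"W_msg{t}"] = glorot((d + self.f_edge, d))
            p[f"b_msg{t}"] = np.zeros(d)
            p[f"W_upd{t}"] = glorot((2 * d, d))
            p[f"b_upd{t}"] = np.zeros(d)
        p["W1"] = glorot((d, H))
        p["b1"] = np.zeros(H)
        p["w2"] = glorot((H, 1))[:, 0]
        p["b2"] = np.zeros(())
        # UCN head xi: multilayer perceptron with linear activations
        p["V1"] = glorot((d, H))
        p["c1"] = np.zeros(H)
        p["v2"] = glorot((H, 1))[:, 0]
        p["c2"] = np.zeros(())
        return p

    def _act(self, a: np.ndarray) -> np.ndarray:
        return np.maximum(a, 0.0) if self.config.activation == "relu" else a

    def _actp(self, a: np.ndarray) -> np.ndarray:
        return (a > 0).astype(np.float64) if self.config.activation == "relu" else np.ones_like(a)

    # -- forward ------------------------------------------------------------

    def forward_packed(self, batch: PackedBatch) -> Dict[str, np.ndarray]:
        """Forward pass on a packed batch; returns the cache used by backward."""
        p = self.params
        cache: Dict[str, np.ndarray] = {}
        a0 = batch.X @ p["W_in"] + p["b_in"]
        h = self._act(a0)
        cache["a0"] = a0
        for t in range(self.config.n_message_passes):
            msg_in = np.concatenate([h[batch.edge_src], batch.EF], axis=1)
            m = msg_in @ p[f"W_msg{t}"] + p[f"b_msg{t}"]
            s = batch.scatter_dst @ m
            upd_in = np.concatenate([h, s], axis=1)
            a = upd_in @ p[f"W_upd{t}"] + p[f"b_upd{t}"]
            cache[f"h{t}"] = h
            cache[f"msg_in{t}"] = msg_in
            cache[f"upd_in{t}"] = upd_in
            cache[f"a{t + 1}"] = a
            h = self._act(a)
        cache["hT"] = h
        g = batch.pool @ h
        z1a = g @ p["W1"] + p["b1"]
        z1 = self._act(z1a)
        yhat = z1 @ p["w2"] + p["b2"]
        cache["g"], cache["z1a"], cache["z1"], cache["yhat"] = g, z1a, z1, yhat
        return cache

    def ucn_readout_packed(self, cache: Dict[str, np.ndarray], mask: np.ndarray) -> float:
        """xi(phi(M(h))): mean of selected embedding rows through the UCN head."""
        if mask.size == 0:
            raise ValueError("UCN readout over an empty atom set is undefined")
        p = self.params
        phi = cache["hT"][mask].mean(axis=0)
        return float((phi @ p["V1"] + p["c1"]) @ p["v2"] + p["c2"])

    def ucn_readouts_batch(
        self, cache: Dict[str, np.ndarray], mask_op: sparse.csr_matrix
    ) -> np.ndarray:
        """All masked readouts at once; ``mask_op`` from :func:`mask_operator`."""
        p = self.params
        phi = mask_op @ cache["hT"]
        return (phi @ p["V1"] + p["c1"]) @ p["v2"] + p["c2"]

    # -- backward -----------------------------------------------------------

    def backward_packed(
        self,
        batch: PackedBatch,
        cache: Dict[str, np.ndarray],
        d_yhat: np.ndarray,
        masked_terms: Optional[Tuple[sparse.csr_matrix, np.ndarray]] = None,
        want_dx: bool = False,
    ) -> Tuple[Dict[str, np.ndarray], Optional[np.ndarray]]:
        """Reverse pass.

        ``d_yhat`` is dL/dyhat per graph; ``masked_terms`` is an optional pair
        (mask operator over nodes, dL/du per mask) for UCN readouts taken from
        this cache.  Returns parameter gradients and (optionally) dL/dX.
        """
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        # prediction head
        z1, z1a, g = cache["z1"], cache["z1a"], cache["g"]
        grads["w2"] += z1.T @ d_yhat
        grads["b2"] += d_yhat.sum()
        dz1 = d_yhat[:, None] * p["w2"][None, :]
        da1 = dz1 * self._actp(z1a)
        grads["W1"] += g.T @ da1
        grads["b1"] += da1.sum(axis=0)
        dg = da1 @ p["W1"].T
        dh = batch.pool.T @ dg

        # UCN head (linear activations)
        if masked_terms is not None:
            mask_op, du = masked_terms
            phi = mask_op @ cache["hT"]
            q = phi @ p["V1"] + p["c1"]
            grads["v2"] += q.T @ du
            grads["c2"] += du.sum()
            dq = du[:, None] * p["v2"][None, :]
            grads["V1"] += phi.T @ dq
            grads["c1"] += dq.sum(axis=0)
            dh += mask_op.T @ (dq @ p["V1"].T)

        # message-passing layers in reverse
        for t in range(self.config.n_message_passes - 1, -1, -1):
            da = dh * self._actp(cache[f"a{t + 1}"])
            grads[f"W_upd{t}"] += cache[f"upd_in{t}"].T @ da
            grads[f"b_upd{t}"] += da.sum(axis=0)
            dupd = da @ p[f"W_upd{t}"].T
            d = self.config.hidden_dim
            dh_prev = np.ascontiguousarray(dupd[:, :d])
            ds = dupd[:, d:]
            if batch.edge_dst.size:
                dm = ds[batch.edge_dst]
                grads[f"W_msg{t}"] += cache[f"msg_in{t}"].T @ dm
                grads[f"b_msg{t}"] += dm.sum(axis=0)
                dmsg_in = dm @ p[f"W_msg{t}"].T
                dh_prev += batch.scatter_src @ dmsg_in[:, :d]
            dh = dh_prev

        da0 = dh * self._actp(cache["a0"])
        grads["W_in"] += batch.X.T @ da0
        grads["b_in"] += da0.sum(axis=0)
        dX = da0 @ p["W_in"].T if want_dx else None
        return grads, dX

    def head_gradient(self, cache: Dict[str, np.ndarray]) -> np.ndarray:
        """d(yhat)/d(pooled embedding g), one row per graph in the cache."""
        p = self.params
        dz1 = self._actp(cache["z1a"]) * p["w2"][None, :]
        return dz1 @ p["W1"].T

    # -- public inference ---------------------------------------------------

    def forward(self, graph: MolecularGraph) -> ForwardResult:
        if graph.node_features.shape[1] != self.f_node:
            raise ValueError(
                f"node feature dimension {graph.node_features.shape[1]} != model's {self.f_node}"
            )
        batch = PackedBatch([graph])
        cache = self.forward_packed(batch)
        return ForwardResult(
            node_embeddings=cache["hT"].copy(), prediction=float(cache["yhat"][0])
        )

    def predict(self, graph: MolecularGraph) -> float:
        return self.forward(graph).prediction

    def ucn_readout(self, h: np.ndarray, uncommon: Iterable[int]) -> float:
        """UCN readout from an externally supplied embedding matrix."""
        idx = np.asarray(sorted(uncommon), dtype=np.int64)
        if idx.size == 0:
            raise ValueError("UCN readout over an empty atom set is undefined")
        p = self.params
        phi = h[idx].mean(axis=0)
        return float((phi @ p["V1"] + p["c1"]) @ p["v2"] + p["c2"])

    # -- serialization ------------------------------------------------------

    def schema_hash(self) -> str:
        payload = json.dumps(
            {"f_node": self.f_node, "f_edge": self.f_edge, "hidden_dim": self.config.hidden_dim},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        blob = {
            "schema_hash": self.schema_hash(),
            "config": asdict(self.config),
            "training_log": self.training_log,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(blob, sort_keys=True))

    @classmethod
    def load(cls, path) -> "TrainedGNN":
        blob = json.loads(Path(path).read_text())
        config = GNNConfig(**blob["config"])
        model = cls(config, params={k: np.asarray(v) for k, v in blob["params"].items()})
        if blob["schema_hash"] != model.schema_hash():
            raise ValueError(
                "checkpoint schema hash mismatch: model was trained under a "
                "different featurization or architecture"
            )
        model.training_log = list(blob["training_log"])
        return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: Dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in sorted(params):
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _pair_graphs(
    pairs: Sequence[CompoundPair], graph_cache: Dict[str, MolecularGraph]
) -> None:
    for p in pairs:
        for rec in (p.record_i, p.record_j):
            if rec.compound_id not in graph_cache:
                graph_cache[rec.compound_id] = featurize(rec.molecule)


def train(
    split: BenchmarkSplit,
    config: GNNConfig,
    graph_cache: Optional[Dict[str, MolecularGraph]] = None,
) -> TrainedGNN:
    """Train a GNN on the training pairs of a split under the configured loss.

    All three loss modes iterate over the same pair batches so that data
    exposure is identical and runs differ only in the objective.  Pairs whose
    uncommon-atom sets are empty on either side contribute only their MSE term
    in UCN mode.  Deterministic given ``config.seed``.
    """
    config.validate()
    pairs = list(split.train_pairs)
    if not pairs:
        raise ValueError("empty training set")

    graph_cache = graph_cache if graph_cache is not None else {}
    _pair_graphs(pairs, graph_cache)

    model = TrainedGNN(config)
    # centre the prediction head on the label mean for faster convergence
    ys = [r.activity for p in pairs for r in (p.record_i, p.record_j)]
    model.params["b2"] = np.asarray(float(np.mean(ys)))

    opt = _Adam(model.params, config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    n_pairs = len(pairs)
    lam = config.lam

    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n_pairs)
        epoch_losses: List[float] = []
        for start in range(0, n_pairs, config.batch_pairs):
            batch_pairs = [pairs[k] for k in order[start : start + config.batch_pairs]]
            P = len(batch_pairs)
            graphs = []
            for pr in batch_pairs:
                graphs.append(graph_cache[pr.record_i.compound_id])
                graphs.append(graph_cache[pr.record_j.compound_id])
            batch = PackedBatch(graphs)
            cache = model.forward_packed(batch)
            yhat = cache["yhat"]

            # UCN readouts for all evaluable pairs of the batch at once
            u_values: Dict[int, Tuple[float, float]] = {}
            mask_op = None
            du = None
            if config.loss_mode == "mse_ucn":
                masks, owners = [], []
                for k, pr in enumerate(batch_pairs):
                    if not pr.evaluable:
                        continue
                    gi, gj = 2 * k, 2 * k + 1
                    masks.append(
                        batch.offsets[gi]
                        + np.asarray(sorted(pr.uncommon_i), dtype=np.int64)
                    )
                    masks.append(
                        batch.offsets[gj]
                        + np.asarray(sorted(pr.uncommon_j), dtype=np.int64)
                    )
                    owners.append(k)
                if masks:
                    mask_op = mask_operator(masks, batch.n_nodes)
                    u_all = model.ucn_readouts_batch(cache, mask_op)
                    du = np.zeros(u_all.size)
                    slot_of = {k: slot for slot, k in enumerate(owners)}
                    for slot, k in enumerate(owners):
                        u_values[k] = (float(u_all[2 * slot]), float(u_all[2 * slot + 1]))

            d_yhat = np.zeros(batch.n_graphs)
            loss_inputs: List[Tuple[PairLossInput, str]] = []
            for k, pr in enumerate(batch_pairs):
                gi, gj = 2 * k, 2 * k + 1
                yi, yj = pr.record_i.activity, pr.record_j.activity
                u_i = u_j = None
                d_yhat[gi] += 2.0 * (yhat[gi] - yi) / P
                d_yhat[gj] += 2.0 * (yhat[gj] - yj) / P
                if config.loss_mode == "mse_ac":
                    e = (yi - yj) - (yhat[gi] - yhat[gj])
                    d_yhat[gi] += -2.0 * lam * e / P
                    d_yhat[gj] += 2.0 * lam * e / P
                elif config.loss_mode == "mse_ucn" and k in u_values:
                    u_i, u_j = u_values[k]
                    e = (u_i - u_j) - (yi - yj)
                    slot = slot_of[k]
                    du[2 * slot] = 2.0 * lam * e / P
                    du[2 * slot + 1] = -2.0 * lam * e / P
                inp = PairLossInput(
                    yhat_i=float(yhat[gi]), yhat_j=float(yhat[gj]), y_i=yi, y_j=yj,
                    u_i=u_i, u_j=u_j,
                )
                mode = config.loss_mode
                if mode == "mse_ucn" and u_i is None:
                    mode = "mse"  # empty-uncommon pair: MSE term only
                loss_inputs.append((inp, mode))

            batch_loss = float(
                np.mean([total_loss(inp, mode, lam) for inp, mode in loss_inputs])
            )
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {batch_loss}; "
                    "lower the learning rate or check the input labels"
                )
            epoch_losses.append(batch_loss)
            masked = (mask_op, du) if mask_op is not None else None
            grads, _ = model.backward_packed(batch, cache, d_yhat, masked)
            opt.step(model.params, grads)
        model.training_log.append(float(np.mean(epoch_losses)))
    return model
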