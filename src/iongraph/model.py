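"""The property-prediction network.

Architecture (mirroring the reference protocol for IL property models):
four stacked graph convolutions (widths 128/256/256/128 by default, ReLU
between layers, dropout after the stack), permutation-invariant sum
readout, concatenation of the standardized measurement conditions
(temperature, optionally pressure), then a fully connected head
(256 → 128 by default) with batch normalization and dropout before the
final scalar layer.

Four interchangeable aggregation families are provided:

* ``gcn`` — degree-normalized weighted average with an implicit unit
  self-loop: x'_v = Σ_{w∈N(v)∪{v}} (e_wv / √(d_v d_w)) · W x_w, where the
  degrees are computed from |edge weight| so the −1 virtual ionic bond
  cannot zero or negate a normalization factor (the signed weight still
  multiplies the message);
* ``gat`` — single-head attention: messages weighted by a softmax over
  incoming edges of a leaky-ReLU attention score, then scaled by the edge
  weight;
* ``kgc`` — un-normalized neighborhood convolution with a separate root
  weight: x'_v = W₁x_v + W₂ Σ_w e_wv·x_w;
* ``mfc`` — fingerprint-style convolution with degree-specific weights:
  x'_v = W₁^{deg(v)} x_v + W₂^{deg(v)} Σ_w x_w (edge weights do not enter,
  matching the published formulation).

Scenario C (two parallel ion graphs) runs both ions through a weight-
shared convolution tower by default; ``separate`` pooling concatenates the
two pooled ion vectors, ``join`` pooling sums them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import sparse

from .errors import ConfigError, ScenarioError, TransferError
from .graphs import NODE_FEATURE_DIM, GraphPair
from .nn import (BatchNorm1d, Dropout, Linear, Module, Tensor, concat,
                 glorot, spmm)

CONV_TYPES = ("gcn", "gat", "kgc", "mfc")
SCENARIOS = ("a", "b", "c")
FEATURE_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    conv_type: str = "gcn"
    conv_widths: tuple = (128, 256, 256, 128)
    head_widths: tuple = (256, 128)
    n_conditions: int = 1
    dropout_rate: float = 0.2
    scenario: str = "a"
    pooling_mode: str | None = None     # scenario c only
    share_towers: bool = True
    mfc_max_degree: int = 6
    gat_negative_slope: float = 0.2

    def __post_init__(self):
        if self.conv_type not in CONV_TYPES:
            raise ConfigError(f"unknown conv type '{self.conv_type}'")
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario '{self.scenario}'")
        if any(w <= 0 for w in tuple(self.conv_widths)
               + tuple(self.head_widths)):
            raise ConfigError("layer widths must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout rate must lie in [0, 1)")
        if self.n_conditions not in (1, 2):
            raise ConfigError("n_conditions must be 1 or 2")
        if (self.scenario == "c") != (self.pooling_mode is not None):
            raise ConfigError(
                "pooling_mode must be given exactly for scenario 'c'")
        if self.pooling_mode not in (None, "separate", "join"):
            raise ConfigError(
                f"unknown pooling mode '{self.pooling_mode}'")

    @property
    def pooled_dim(self) -> int:
        base = self.conv_widths[-1]
        if self.scenario == "c" and self.pooling_mode == "separate":
            return 2 * base
        return base


# ---------------------------------------------------------------------------
# graph batching
# ---------------------------------------------------------------------------

class BatchedGraphs:
    """Block-diagonal batch of molecular graphs (shared node index space)."""

    def __init__(self, graphs):
        if not graphs:
            raise ScenarioError("cannot batch zero graphs")
        xs, srcs, dsts, ws, membership = [], [], [], [], []
        offset = 0
        for gid, g in enumerate(graphs):
            n = g.n_nodes
            xs.append(g.node_features)
            if g.n_edges:
                srcs.append(g.edge_index[:, 0] + offset)
                dsts.append(g.edge_index[:, 1] + offset)
                ws.append(g.edge_weights)
            membership.append(np.full(n, gid))
            offset += n
        self.x = np.vstack(xs)
        self.src = (np.concatenate(srcs) if srcs
                    else np.empty(0, dtype=int))
        self.dst = (np.concatenate(dsts) if dsts
                    else np.empty(0, dtype=int))
        self.w = np.concatenate(ws) if ws else np.empty(0)
        self.node_graph = np.concatenate(membership)
        self.n_nodes = offset
        self.n_graphs = len(graphs)
        self._cache = {}

    # cached message-passing constants ---------------------------------
    def with_self_loops(self):
        """(src, dst, w) augmented with unit self-loops."""
        if "loops" not in self._cache:
            loops = np.arange(self.n_nodes)
            self._cache["loops"] = (
                np.concatenate([self.src, loops]),
                np.concatenate([self.dst, loops]),
                np.concatenate([self.w, np.ones(self.n_nodes)]),
            )
        return self._cache["loops"]

    def gcn_coefficients(self):
        """Symmetric-normalization factors e_wv/√(d_w d_v) with degrees
        accumulated from |edge weight| over the self-loop-augmented graph."""
        if "gcn" not in self._cache:
            src, dst, w = self.with_self_loops()
            deg = np.zeros(self.n_nodes)
            np.add.at(deg, dst, np.abs(w))
            coef = w / np.sqrt(deg[src] * deg[dst])
            self._cache["gcn"] = coef
        return self._cache["gcn"]

    def neighbor_degrees(self) -> np.ndarray:
        if "deg" not in self._cache:
            self._cache["deg"] = np.bincount(
                self.dst, minlength=self.n_nodes).astype(int)
        return self._cache["deg"]

    # sparse operators (rows = destination nodes) ----------------------
    def _sparse(self, key, src, dst, values):
        if key not in self._cache:
            matrix = sparse.csr_matrix(
                (values, (dst, src)), shape=(self.n_nodes, self.n_nodes))
            self._cache[key] = (matrix, matrix.T.tocsr())
        return self._cache[key]

    def gcn_operator(self):
        src, dst, _ = self.with_self_loops()
        return self._sparse("gcn_op", src, dst, self.gcn_coefficients())

    def weighted_operator(self):
        return self._sparse("w_op", self.src, self.dst, self.w)

    def unweighted_operator(self):
        return self._sparse("u_op", self.src, self.dst,
                            np.ones(len(self.src)))

    def pooling_operator(self):
        if "pool" not in self._cache:
            matrix = sparse.csr_matrix(
                (np.ones(self.n_nodes),
                 (self.node_graph, np.arange(self.n_nodes))),
                shape=(self.n_graphs, self.n_nodes))
            self._cache["pool"] = (matrix, matrix.T.tocsr())
        return self._cache["pool"]


class PairBatch:
    """Scenario-C batch: parallel cation and anion batches."""

    def __init__(self, pairs):
        modes = {p.pooling_mode for p in pairs}
        if len(modes) != 1:
            raise ScenarioError("mixed pooling modes in one batch")
        self.pooling_mode = modes.pop()
        self.cation = BatchedGraphs([p.cation_graph for p in pairs])
        self.anion = BatchedGraphs([p.anion_graph for p in pairs])
        self.n_graphs = len(pairs)


def batch_inputs(items) -> "BatchedGraphs | PairBatch":
    first = items[0]
    if isinstance(first, GraphPair):
        return PairBatch(items)
    return BatchedGraphs(items)


# ---------------------------------------------------------------------------
# convolution layers
# ---------------------------------------------------------------------------

class GCNConv(Module):
    def __init__(self, d_in, d_out, rng):
        self.W = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, h: Tensor, batch: BatchedGraphs) -> Tensor:
        op, op_t = batch.gcn_operator()
        return spmm(op, h @ self.W, op_t) + self.b


class GATConv(Module):
    def __init__(self, d_in, d_out, rng, negative_slope=0.2):
        self.W = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        self.a_src = Tensor(glorot(rng, d_out, 1), requires_grad=True)
        self.a_dst = Tensor(glorot(rng, d_out, 1), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)
        self.negative_slope = negative_slope

    def __call__(self, h: Tensor, batch: BatchedGraphs) -> Tensor:
        src, dst, w = batch.with_self_loops()
        xw = h @ self.W
        score = (xw @ self.a_src).take(src) + (xw @ self.a_dst).take(dst)
        score = score.leaky_relu(self.negative_slope)
        # per-destination softmax; the subtracted max is a constant shift
        seg_max = np.full((batch.n_nodes, 1), -np.inf)
        np.maximum.at(seg_max, dst, score.data)
        expd = (score - seg_max[dst]).exp()
        denom = expd.segment_sum(dst, batch.n_nodes)
        att = expd / denom.take(dst)
        msg = xw.take(src) * att * w[:, None]
        return msg.segment_sum(dst, batch.n_nodes) + self.b


class KGConv(Module):
    """Neighborhood convolution without degree normalization."""

    def __init__(self, d_in, d_out, rng):
        self.W_root = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        self.W_nbr = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, h: Tensor, batch: BatchedGraphs) -> Tensor:
        op, op_t = batch.weighted_operator()
        return h @ self.W_root + spmm(op, h, op_t) @ self.W_nbr + self.b


class MFConv(Module):
    """Fingerprint convolution: degree-specific root/neighbor weights."""

    def __init__(self, d_in, d_out, rng, max_degree=6):
        self.max_degree = max_degree
        self.W_root = [Tensor(glorot(rng, d_in, d_out), requires_grad=True)
                       for _ in range(max_degree + 1)]
        self.W_nbr = [Tensor(glorot(rng, d_in, d_out), requires_grad=True)
                      for _ in range(max_degree + 1)]
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def parameters(self):
        return self.W_root + self.W_nbr + [self.b]

    def __call__(self, h: Tensor, batch: BatchedGraphs) -> Tensor:
        op, op_t = batch.unweighted_operator()
        agg = spmm(op, h, op_t)
        deg = np.minimum(batch.neighbor_degrees(), self.max_degree)
        out = None
        for d in range(self.max_degree + 1):
            idx = np.flatnonzero(deg == d)
            if idx.size == 0:
                continue
            part = (h.take(idx) @ self.W_root[d]
                    + agg.take(idx) @ self.W_nbr[d]).put(idx, batch.n_nodes)
            out = part if out is None else out + part
        return out + self.b


def _make_conv(conv_type, d_in, d_out, rng, config):
    if conv_type == "gcn":
        return GCNConv(d_in, d_out, rng)
    if conv_type == "gat":
        return GATConv(d_in, d_out, rng, config.gat_negative_slope)
    if conv_type == "kgc":
        return KGConv(d_in, d_out, rng)
    return MFConv(d_in, d_out, rng, config.mfc_max_degree)


# ---------------------------------------------------------------------------
# the regressor
# ---------------------------------------------------------------------------

class GNNRegressor(Module):
    """Graph convolutions + sum readout + condition-aware regression head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        dims = [NODE_FEATURE_DIM] + list(config.conv_widths)
        self.convs = [_make_conv(config.conv_type, dims[i], dims[i + 1],
                                 rng, config)
                      for i in range(len(config.conv_widths))]
        if config.scenario == "c" and not config.share_towers:
            self.convs_anion = [
                _make_conv(config.conv_type, dims[i], dims[i + 1], rng,
                           config)
                for i in range(len(config.conv_widths))]
        else:
            self.convs_anion = None
        head_dims = ([config.pooled_dim + config.n_conditions]
                     + list(config.head_widths))
        self.head = [Linear(head_dims[i], head_dims[i + 1], rng)
                     for i in range(len(config.head_widths))]
        self.batch_norm = BatchNorm1d(head_dims[-1])
        self.dropout = Dropout(config.dropout_rate)
        self.out = Linear(head_dims[-1], 1, rng)
        # standardization constants, fixed from the training split
        self.cond_mean = np.zeros(config.n_conditions)
        self.cond_std = np.ones(config.n_conditions)
        self.y_mean = 0.0
        self.y_std = 1.0

    # -- forward -------------------------------------------------------
    def _tower(self, batch: BatchedGraphs, convs, training, rng) -> Tensor:
        h = Tensor(batch.x)
        for conv in convs:
            h = conv(h, batch).relu()
        h = self.dropout(h, training, rng)
        pool, pool_t = batch.pooling_operator()
        return spmm(pool, h, pool_t)

    def pooled(self, batch, training=False, rng=None) -> Tensor:
        if isinstance(batch, PairBatch):
            if self.config.scenario != "c":
                raise ScenarioError(
                    "graph pairs require a scenario-'c' model")
            anion_convs = (self.convs if self.convs_anion is None
                           else self.convs_anion)
            pc = self._tower(batch.cation, self.convs, training, rng)
            pa = self._tower(batch.anion, anion_convs, training, rng)
            if batch.pooling_mode == "separate":
                return concat([pc, pa], axis=1)
            return pc + pa
        if self.config.scenario == "c":
            raise ScenarioError("scenario-'c' models require graph pairs")
        return self._tower(batch, self.convs, training, rng)

    def forward(self, batch, conditions_std: np.ndarray,
                training: bool = False, rng=None) -> Tensor:
        """Standardized prediction for a batch.

        `conditions_std` must already be z-scored with the stored training
        statistics; the returned tensor is on the standardized target
        scale.
        """
        conditions_std = np.atleast_2d(conditions_std)
        if conditions_std.shape[1] != self.config.n_conditions:
            raise ConfigError(
                f"expected {self.config.n_conditions} conditions, got "
                f"{conditions_std.shape[1]}")
        pooled = self.pooled(batch, training, rng)
        z = concat([pooled, Tensor(conditions_std)], axis=1)
        for layer in self.head:
            z = layer(z).relu()
        z = self.batch_norm(z, training)
        z = self.dropout(z, training, rng)
        return self.out(z)

    # -- user-facing prediction ----------------------------------------
    def standardize_conditions(self, conditions: np.ndarray) -> np.ndarray:
        conditions = np.atleast_2d(conditions)
        if conditions.shape[1] != self.config.n_conditions:
            raise ConfigError(
                f"expected {self.config.n_conditions} conditions, got "
                f"{conditions.shape[1]}")
        return (conditions - self.cond_mean) / self.cond_std

    def predict(self, graph_or_pair, conditions) -> float:
        """Property value (dataset units) for one ion-pair graph at given
        measurement conditions."""
        batch = batch_inputs([graph_or_pair])
        cond = self.standardize_conditions(
            np.asarray(conditions, dtype=float).reshape(1, -1))
        yhat = self.forward(batch, cond, training=False)
        return float(yhat.data[0, 0] * self.y_std + self.y_mean)

    def predict_batch(self, items, conditions) -> np.ndarray:
        batch = batch_inputs(list(items))
        cond = self.standardize_conditions(np.asarray(conditions, float))
        yhat = self.forward(batch, cond, training=False)
        return yhat.data[:, 0] * self.y_std + self.y_mean

    # -- parameter partitions -------------------------------------------
    def conv_parameters(self) -> list:
        params = [p for conv in self.convs for p in conv.parameters()]
        if self.convs_anion is not None:
            params += [p for conv in self.convs_anion
                       for p in conv.parameters()]
        return params

    def head_parameters(self) -> list:
        params = [p for layer in self.head for p in layer.parameters()]
        params += self.batch_norm.parameters() + self.out.parameters()
        return params

    def parameters(self) -> list:
        return self.conv_parameters() + self.head_parameters()

    # -- persistence -----------------------------------------------------
    def state_arrays(self) -> dict:
        state = {f"param_{i}": p.data
                 for i, p in enumerate(self.parameters())}
        state["bn_running_mean"] = self.batch_norm.running_mean
        state["bn_running_var"] = self.batch_norm.running_var
        state["cond_mean"] = self.cond_mean
        state["cond_std"] = self.cond_std
        state["y_stats"] = np.array([self.y_mean, self.y_std])
        return state

    def load_state_arrays(self, state: dict):
        for i, p in enumerate(self.parameters()):
            arr = np.asarray(state[f"param_{i}"])
            if arr.shape != p.data.shape:
                raise TransferError(
                    f"parameter {i} shape mismatch: {arr.shape} vs "
                    f"{p.data.shape}")
            p.data = arr.copy()
        self.batch_norm.running_mean = np.asarray(
            state["bn_running_mean"]).copy()
        self.batch_norm.running_var = np.asarray(
            state["bn_running_var"]).copy()
        self.cond_mean = np.asarray(state["cond_mean"]).copy()
        self.cond_std = np.asarray(state["cond_std"]).copy()
        self.y_mean, self.y_std = (float(state["y_stats"][0]),
                                   float(state["y_stats"][1]))


def build_model(config: ModelConfig, seed: int = 0) -> GNNRegressor:
    """Construct a regressor with seeded Glorot initialization."""
    return GNNRegressor(config, seed=seed)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: GNNRegressor, path) -> None:
    """Serialize parameters + config + standardization constants (.npz)."""
    meta = {"config": asdict(model.config),
            "feature_schema_version": FEATURE_SCHEMA_VERSION}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8),
        **model.state_arrays())


def load_checkpoint(path) -> GNNRegressor:
    with np.load(path) as payload:
        meta = json.loads(bytes(payload["__meta__"]).decode())
        if meta["feature_schema_version"] != FEATURE_SCHEMA_VERSION:
            raise TransferError(
                "checkpoint was written with an incompatible feature "
                "schema")
        cfg = meta["config"]
        cfg["conv_widths"] = tuple(cfg["conv_widths"])
        cfg["head_widths"] = tuple(cfg["head_widths"])
        model = GNNRegressor(ModelConfig(**cfg), seed=0)
        model.load_state_arrays({k: payload[k] for k in payload.files
                                 if k != "__meta__"})
    return model
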