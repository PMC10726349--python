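"""Conversion of ion geometries into model-ready molecular graphs.

Three ion-pair-to-graph scenarios are supported:

* scenario A (``merged_a``) — each ion is converted to its own graph and
  the two are merged block-diagonally (cation block first, no crossing
  edges), optionally bridged by a *virtual ionic bond*;
* scenario B (``joint_b``) — a single graph built from the jointly relaxed
  cation+anion geometry (cation atoms indexed first), same optional bond;
* scenario C (``GraphPair``) — the two ion graphs stay separate and are
  combined only after pooling (``separate`` = concatenate the pooled ion
  vectors, ``join`` = sum node embeddings across both ions).

The virtual ionic bond is an artificial edge of weight −1 linking the
first cation atom to the last anion atom, appended at the end of the edge
list, to ease message flow between the two otherwise disconnected ion
subgraphs.

Node feature layout (d=8, fixed order):
``[atomic_number, h_count, sp, sp2, sp3, other, aromatic_flag, charge]``.
Edge weights equal the bond order (1, 2, 3) or 1.5 for aromatic bonds;
every chemical bond is stored as two directed arcs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .errors import FeaturizationError, ScenarioError
from .ions import ChargeVector, IonGeometry

NODE_FEATURE_DIM = 8
AROMATIC_EDGE_WEIGHT = 1.5
IONIC_BOND_WEIGHT = -1.0
SCENARIO_TAGS = ("single_ion", "merged_a", "joint_b")

_HYB_ONEHOT = {"sp": 0, "sp2": 1, "sp3": 2, "other": 3}


@dataclass(frozen=True)
class MolecularGraph:
    """Node-feature matrix plus weighted directed edge list."""

    node_features: np.ndarray        # (n, 8)
    edge_index: np.ndarray           # (m, 2) directed (src, dst)
    edge_weights: np.ndarray         # (m,)
    cation_node_count: int
    scenario_tag: str
    has_ionic_bond: bool = False

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[0]

    def validate(self) -> "MolecularGraph":
        n = self.n_nodes
        if self.scenario_tag not in SCENARIO_TAGS:
            raise ScenarioError(f"unknown scenario '{self.scenario_tag}'")
        if n < 1:
            raise FeaturizationError("graph must contain at least one node")
        if self.node_features.shape[1] != NODE_FEATURE_DIM:
            raise FeaturizationError(
                f"expected {NODE_FEATURE_DIM} node features, got "
                f"{self.node_features.shape[1]}")
        if not (0 < self.cation_node_count <= n):
            raise FeaturizationError("cation node count out of range")
        if self.n_edges:
            if self.edge_index.min() < 0 or self.edge_index.max() >= n:
                raise FeaturizationError("edge index out of range")
            if np.any(self.edge_index[:, 0] == self.edge_index[:, 1]):
                raise FeaturizationError("self-loops must not be stored")
        return self

    def dense_adjacency(self) -> np.ndarray:
        """Weighted dense adjacency matrix (test/oracle rendering)."""
        adj = np.zeros((self.n_nodes, self.n_nodes))
        for (src, dst), w in zip(self.edge_index, self.edge_weights):
            adj[src, dst] = w
        return adj

    def crossing_arcs(self) -> np.ndarray:
        """Directed arcs that cross the cation/anion index boundary."""
        if self.n_edges == 0:
            return np.empty((0, 2), dtype=int)
        c = self.cation_node_count
        mask = ((self.edge_index[:, 0] < c) ^ (self.edge_index[:, 1] < c))
        return self.edge_index[mask]

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "node_features": self.node_features.tolist(),
            "edge_index": self.edge_index.tolist(),
            "edge_weights": self.edge_weights.tolist(),
            "cation_node_count": int(self.cation_node_count),
            "scenario_tag": self.scenario_tag,
            "has_ionic_bond": bool(self.has_ionic_bond),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MolecularGraph":
        return cls(
            node_features=np.asarray(payload["node_features"], dtype=float),
            edge_index=np.asarray(payload["edge_index"],
                                  dtype=int).reshape(-1, 2),
            edge_weights=np.asarray(payload["edge_weights"], dtype=float),
            cation_node_count=int(payload["cation_node_count"]),
            scenario_tag=payload["scenario_tag"],
            has_ionic_bond=bool(payload.get("has_ionic_bond", False)),
        ).validate()

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "MolecularGraph":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class GraphPair:
    """Scenario-C container: two single-ion graphs pooled in parallel."""

    cation_graph: MolecularGraph
    anion_graph: MolecularGraph
    pooling_mode: str

    def __post_init__(self):
        if self.pooling_mode not in ("separate", "join"):
            raise ScenarioError(
                f"unknown pooling mode '{self.pooling_mode}'")
        for g in (self.cation_graph, self.anion_graph):
            if g.scenario_tag != "single_ion":
                raise ScenarioError(
                    "graph pairs are built from single-ion graphs")


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def _atom_aromatic_flags(geom: IonGeometry) -> np.ndarray:
    flags = np.zeros(geom.n_atoms, dtype=bool)
    for i, j, _, aromatic in geom.bonds:
        if aromatic:
            flags[i] = flags[j] = True
    return flags


def _features(geom: IonGeometry, charges: ChargeVector) -> np.ndarray:
    if len(charges.values) != geom.n_atoms:
        raise FeaturizationError(
            f"charge vector length {len(charges.values)} does not match "
            f"{geom.n_atoms} heavy atoms")
    x = np.zeros((geom.n_atoms, NODE_FEATURE_DIM))
    x[:, 0] = geom.elements
    x[:, 1] = geom.h_counts
    for i, hyb in enumerate(geom.hybridizations):
        x[i, 2 + _HYB_ONEHOT.get(hyb, 3)] = 1.0
    x[:, 6] = _atom_aromatic_flags(geom)
    x[:, 7] = charges.values
    return x


def _edges(geom: IonGeometry):
    src, dst, w = [], [], []
    for i, j, order, aromatic in geom.bonds:
        weight = AROMATIC_EDGE_WEIGHT if aromatic else float(order)
        src += [i, j]
        dst += [j, i]
        w += [weight, weight]
    return (np.array(list(zip(src, dst)), dtype=int).reshape(-1, 2),
            np.array(w))


def build_ion_graph(geom: IonGeometry,
                    charges: ChargeVector) -> MolecularGraph:
    """Featurize one ion as a single-ion molecular graph."""
    edge_index, edge_weights = _edges(geom)
    return MolecularGraph(
        node_features=_features(geom, charges),
        edge_index=edge_index,
        edge_weights=edge_weights,
        cation_node_count=geom.n_atoms,
        scenario_tag="single_ion",
    ).validate()


def merge_block_diagonal(g_cat: MolecularGraph,
                         g_an: MolecularGraph) -> MolecularGraph:
    """Scenario A: stack two ion graphs block-diagonally (cation first)."""
    for role, g in (("cation", g_cat), ("anion", g_an)):
        if g.scenario_tag != "single_ion":
            raise ScenarioError(
                f"block-diagonal merge needs single-ion graphs, the "
                f"{role} graph is '{g.scenario_tag}'")
        if g.n_nodes < 1:
            raise FeaturizationError(f"{role} graph is empty")
    n_cat = g_cat.n_nodes
    edge_index = np.vstack([
        g_cat.edge_index.reshape(-1, 2),
        g_an.edge_index.reshape(-1, 2) + n_cat,
    ])
    return MolecularGraph(
        node_features=np.vstack([g_cat.node_features, g_an.node_features]),
        edge_index=edge_index,
        edge_weights=np.concatenate([g_cat.edge_weights, g_an.edge_weights]),
        cation_node_count=n_cat,
        scenario_tag="merged_a",
    ).validate()


def add_virtual_ionic_bond(g: MolecularGraph) -> MolecularGraph:
    """Append the weight −1 cation(first atom)↔anion(last atom) edge.

    Both directed arcs are appended at the end of the edge list; the prior
    arcs are untouched.  Only meaningful when cation and anion live in one
    graph, so single-ion graphs (scenario C components) are rejected.
    """
    if g.scenario_tag not in ("merged_a", "joint_b"):
        raise ScenarioError(
            "Virtual ionic bonds are applicable only in scenarios A and B")
    if g.has_ionic_bond:
        raise ScenarioError("the graph already carries a virtual ionic bond")
    first_cation, last_anion = 0, g.n_nodes - 1
    edge_index = np.vstack([
        g.edge_index.reshape(-1, 2),
        [[first_cation, last_anion], [last_anion, first_cation]],
    ])
    edge_weights = np.concatenate(
        [g.edge_weights, [IONIC_BOND_WEIGHT, IONIC_BOND_WEIGHT]])
    return replace(g, edge_index=edge_index, edge_weights=edge_weights,
                   has_ionic_bond=True).validate()


def build_joint_graph(joint_geom: IonGeometry, charges: ChargeVector,
                      cation_atom_count: int | None = None) -> MolecularGraph:
    """Scenario B: one graph from a jointly relaxed cation+anion geometry."""
    if cation_atom_count is None:
        cation_atom_count = joint_geom.cation_atom_count
    if cation_atom_count is None or not (
            0 < cation_atom_count < joint_geom.n_atoms):
        raise FeaturizationError(
            f"cation atom count {cation_atom_count} out of range for a "
            f"{joint_geom.n_atoms}-atom joint geometry")
    edge_index, edge_weights = _edges(joint_geom)
    return MolecularGraph(
        node_features=_features(joint_geom, charges),
        edge_index=edge_index,
        edge_weights=edge_weights,
        cation_node_count=int(cation_atom_count),
        scenario_tag="joint_b",
    ).validate()


def build_graph_pair(g_cat: MolecularGraph, g_an: MolecularGraph,
                     pooling_mode: str) -> GraphPair:
    """Scenario C: keep the two ion graphs separate until pooling."""
    return GraphPair(cation_graph=g_cat, anion_graph=g_an,
                     pooling_mode=pooling_mode)
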