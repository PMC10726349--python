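"""Network contracts: oracle equivalence, invariances, shapes, persistence."""

import numpy as np
import pytest

import iongraph as ig
from iongraph.errors import ConfigError, ScenarioError
from iongraph.graphs import MolecularGraph
from iongraph.model import BatchedGraphs, GCNConv
from iongraph.nn import Tensor

from conftest import dense_gcn_forward, random_small_graph


def as_graph(x, edge_index, edge_weights, cation_count=None,
             tag="single_ion"):
    return MolecularGraph(
        node_features=np.asarray(x, dtype=float),
        edge_index=np.asarray(edge_index, dtype=int).reshape(-1, 2),
        edge_weights=np.asarray(edge_weights, dtype=float),
        cation_node_count=(len(x) if cation_count is None
                           else cation_count),
        scenario_tag=tag)


def permuted_graph(g, perm):
    """Relabel node i -> perm[i], keeping edge order."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return MolecularGraph(
        node_features=g.node_features[inv],
        edge_index=(perm[g.edge_index] if g.n_edges
                    else g.edge_index),
        edge_weights=g.edge_weights,
        cation_node_count=g.cation_node_count,
        scenario_tag=g.scenario_tag)


class TestGCNLayerOracle:
    def test_matches_dense_brute_force_on_200_random_graphs(self):
        rng = np.random.default_rng(123)
        layer = GCNConv(8, 5, np.random.default_rng(0))
        layer.b.data[:] = 0.0
        for _ in range(200):
            x, ei, ew = random_small_graph(rng, max_nodes=6, d_in=8)
            batch = BatchedGraphs([as_graph(x, ei, ew)])
            out = layer(Tensor(x), batch).data
            expected = dense_gcn_forward(x, ei, ew, layer.W.data)
            assert np.allclose(out, expected, atol=1e-6)

    def test_isolated_node_with_identity_weights_is_identity(self):
        layer = GCNConv(8, 8, np.random.default_rng(0))
        layer.W.data = np.eye(8)
        layer.b.data[:] = 0.0
        x = np.arange(8.0).reshape(1, 8)
        batch = BatchedGraphs([as_graph(x, np.empty((0, 2)),
                                        np.empty(0))])
        out = layer(Tensor(x), batch).data
        assert np.allclose(out, x)   # self-loop only, c = 1

    def test_two_node_path_hand_check(self):
        layer = GCNConv(8, 8, np.random.default_rng(0))
        layer.W.data = np.eye(8)
        layer.b.data[:] = 0.0
        x = np.zeros((2, 8))
        x[0, 0], x[1, 0] = 1.0, 3.0
        batch = BatchedGraphs([as_graph(x, [[0, 1], [1, 0]], [1.0, 1.0])])
        out = layer(Tensor(x), batch).data
        # deg = 2 for both nodes; out_v = x_v/2 + x_w/2
        assert out[0, 0] == pytest.approx(0.5 + 1.5)
        assert out[1, 0] == pytest.approx(1.5 + 0.5)

    def test_layer_is_permutation_equivariant(self):
        rng = np.random.default_rng(77)
        layer = GCNConv(8, 4, np.random.default_rng(1))
        x, ei, ew = random_small_graph(rng, max_nodes=6, d_in=8)
        if len(x) < 2:
            return
        g = as_graph(x, ei, ew)
        perm = rng.permutation(len(x))
        gp = permuted_graph(g, perm)
        out = layer(Tensor(g.node_features), BatchedGraphs([g])).data
        out_p = layer(Tensor(gp.node_features),
                      BatchedGraphs([gp])).data
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        assert np.allclose(out_p, out[inv], atol=1e-10)


@pytest.mark.parametrize("conv_type", ["gcn", "gat", "kgc", "mfc"])
class TestPredictInvariances:
    def make_model(self, conv_type):
        cfg = ig.ModelConfig(conv_type=conv_type,
                             conv_widths=(8, 16, 16, 8),
                             head_widths=(16, 8))
        return ig.build_model(cfg, seed=5)

    def test_prediction_invariant_to_node_relabeling(self, conv_type,
                                                     library_graphs_a):
        model = self.make_model(conv_type)
        rng = np.random.default_rng(3)
        for g in list(library_graphs_a.values())[:4]:
            perm = rng.permutation(g.n_nodes)
            y = model.predict(g, [300.0])
            y_p = model.predict(permuted_graph(g, perm), [300.0])
            assert y == pytest.approx(y_p, abs=1e-6)

    def test_negative_ionic_bond_weight_stays_finite(self, conv_type,
                                                     library_graphs_a):
        model = self.make_model(conv_type)
        for g in library_graphs_a.values():
            assert g.has_ionic_bond
            assert np.isfinite(model.predict(g, [300.0]))

    def test_eval_mode_is_bitwise_deterministic(self, conv_type,
                                                library_graphs_a):
        model = self.make_model(conv_type)
        g = next(iter(library_graphs_a.values()))
        assert model.predict(g, [310.0]) == model.predict(g, [310.0])


class TestReadoutAndConditions:
    def test_sum_readout_equals_manual_sum(self, small_model_config):
        model = ig.build_model(small_model_config, seed=0)
        rng = np.random.default_rng(1)
        x, ei, ew = random_small_graph(rng, max_nodes=5, d_in=8)
        g = as_graph(x, ei, ew)
        batch = BatchedGraphs([g])
        h = Tensor(x)
        for conv in model.convs:
            h = conv(h, batch).relu()
        pooled = model.pooled(batch).data
        assert np.allclose(pooled, h.data.sum(axis=0, keepdims=True))

    def test_separate_pooling_concatenates_widths(self, emim_cl):
        cfg = ig.ModelConfig(conv_widths=(8, 16, 16, 8),
                             head_widths=(16, 8), scenario="c",
                             pooling_mode="separate")
        model = ig.build_model(cfg, seed=0)
        feat = ig.GraphFeaturizer(scenario="c", ionic_bond=False,
                                  pooling_mode="separate")
        pair_graph = feat(emim_cl)
        from iongraph.model import PairBatch
        pooled = model.pooled(PairBatch([pair_graph])).data
        assert pooled.shape == (1, 16)      # 2 × last conv width

    def test_join_and_separate_share_output_shape(self, emim_cl):
        outputs = {}
        for mode in ("separate", "join"):
            cfg = ig.ModelConfig(conv_widths=(8, 16, 16, 8),
                                 head_widths=(16, 8), scenario="c",
                                 pooling_mode=mode)
            model = ig.build_model(cfg, seed=0)
            feat = ig.GraphFeaturizer(scenario="c", ionic_bond=False,
                                      pooling_mode=mode)
            outputs[mode] = model.predict(feat(emim_cl), [298.15])
        assert all(np.isscalar(v) or np.ndim(v) == 0
                   for v in outputs.values())

    def test_conditions_change_the_prediction(self, library_graphs_a):
        model = ig.build_model(ig.ModelConfig(conv_widths=(8, 16, 16, 8),
                                              head_widths=(16, 8)),
                               seed=2)
        g = next(iter(library_graphs_a.values()))
        assert (model.predict(g, [280.0])
                != pytest.approx(model.predict(g, [360.0])))

    def test_condition_count_mismatch_rejected(self, library_graphs_a):
        model = ig.build_model(ig.ModelConfig(conv_widths=(8, 16, 16, 8),
                                              head_widths=(16, 8),
                                              n_conditions=2), seed=0)
        g = next(iter(library_graphs_a.values()))
        with pytest.raises(ConfigError):
            model.predict(g, [300.0])


class TestBuildModel:
    def test_parameter_count_is_a_pure_function_of_config(self):
        cfg = ig.ModelConfig(conv_widths=(8, 16, 16, 8),
                             head_widths=(16, 8))
        assert (ig.build_model(cfg, seed=0).n_parameters()
                == ig.build_model(cfg, seed=99).n_parameters())

    def test_default_gcn_parameter_count_audit(self):
        model = ig.build_model(ig.ModelConfig(), seed=0)
        conv = (8 * 128 + 128) + (128 * 256 + 256) \
            + (256 * 256 + 256) + (256 * 128 + 128)
        head = ((128 + 1) * 256 + 256) + (256 * 128 + 128)
        bn = 2 * 128
        out = 128 * 1 + 1
        assert model.n_parameters() == conv + head + bn + out

    def test_shared_towers_cost_no_extra_parameters(self):
        base = ig.ModelConfig(conv_widths=(8, 16, 16, 8),
                              head_widths=(16, 8))
        shared = ig.ModelConfig(conv_widths=(8, 16, 16, 8),
                                head_widths=(16, 8), scenario="c",
                                pooling_mode="join")
        unshared = ig.ModelConfig(conv_widths=(8, 16, 16, 8),
                                  head_widths=(16, 8), scenario="c",
                                  pooling_mode="join",
                                  share_towers=False)
        n_conv = sum(p.data.size for p in
                     ig.build_model(base, 0).conv_parameters())
        assert (ig.build_model(shared, 0).n_parameters() + n_conv
                == ig.build_model(unshared, 0).n_parameters())

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            ig.ModelConfig(dropout_rate=1.0)
        with pytest.raises(ConfigError):
            ig.ModelConfig(conv_type="sage")
        with pytest.raises(ConfigError):
            ig.ModelConfig(scenario="a", pooling_mode="join")
        with pytest.raises(ConfigError):
            ig.ModelConfig(scenario="c")

    def test_scenario_mismatch_raises(self, library_graphs_a, emim_cl):
        model_c = ig.build_model(
            ig.ModelConfig(conv_widths=(8,), head_widths=(8,),
                           scenario="c", pooling_mode="join"), 0)
        g = next(iter(library_graphs_a.values()))
        with pytest.raises(ScenarioError):
            model_c.predict(g, [300.0])


class TestCheckpoint:
    def test_round_trip_reproduces_predictions_bitwise(
            self, tmp_path, library_graphs_a, small_model_config):
        model = ig.build_model(small_model_config, seed=4)
        model.y_mean, model.y_std = 42.0, 3.5
        model.cond_mean[:] = 300.0
        model.cond_std[:] = 25.0
        path = tmp_path / "model.npz"
        ig.save_checkpoint(model, path)
        restored = ig.load_checkpoint(path)
        for g in library_graphs_a.values():
            assert restored.predict(g, [305.0]) == model.predict(
                g, [305.0])
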