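"""Training loop, metric formulas, aggregation, transfer contracts."""

import numpy as np
import pytest

import iongraph as ig
from iongraph.errors import ConfigError, TransferError
from iongraph.training import compute_metrics, initialize_from


class TestComputeMetrics:
    def test_perfect_prediction(self):
        assert compute_metrics([1, 2, 3], [1, 2, 3]) == (1.0, 0.0, 0.0)

    def test_two_point_worked_example(self):
        r2, rmse, mare = compute_metrics([1.0, 2.0], [2.0, 1.0])
        assert r2 == pytest.approx(-3.0)
        assert rmse == pytest.approx(1.0)
        assert mare == pytest.approx(0.75)

    def test_constant_targets_undefined_r2(self):
        with pytest.raises(ConfigError):
            compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_zero_target_undefined_mare(self):
        with pytest.raises(ConfigError):
            compute_metrics([0.0, 1.0], [1.0, 1.0])

    def test_r2_one_iff_rmse_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.normal(size=10)
            noisy = y + rng.normal(size=10) * rng.choice([0.0, 0.3])
            r2, rmse, _ = compute_metrics(np.abs(y) + 1.0,
                                          np.abs(y) + 1.0 + (noisy - y))
            assert (r2 == 1.0) == (rmse == 0.0)


@pytest.fixture(scope="module")
def small_cfg():
    return ig.ModelConfig(conv_widths=(8, 16, 16, 8), head_widths=(16, 8))


class TestTrainModel:
    def test_loss_decreases_within_first_scheduler_period(self, tiny_task,
                                                          small_cfg):
        finals = []
        for seed in range(3):
            model = ig.build_model(small_cfg, seed=seed)
            cfg = ig.TrainConfig(epochs=20, scheduler_period=20,
                                 batch_size=16)
            _, metrics = ig.train_model(model, tiny_task["ds"],
                                        tiny_task["graphs"],
                                        tiny_task["split"], cfg,
                                        seed=seed)
            curve = metrics.loss_curve
            assert np.all(np.isfinite(curve))
            finals.append(curve[-1] < curve[0])
        assert np.median(finals) == 1.0

    def test_same_seed_reproduces_the_loss_curve_bitwise(self, tiny_task,
                                                         small_cfg):
        curves = []
        for _ in range(2):
            model = ig.build_model(small_cfg, seed=7)
            cfg = ig.TrainConfig(epochs=4, scheduler_period=4,
                                 batch_size=16)
            _, metrics = ig.train_model(model, tiny_task["ds"],
                                        tiny_task["graphs"],
                                        tiny_task["split"], cfg, seed=7)
            curves.append(metrics.loss_curve)
        assert np.array_equal(curves[0], curves[1])

    def test_standardization_constants_come_from_train_split(
            self, tiny_task, small_cfg):
        model = ig.build_model(small_cfg, seed=0)
        cfg = ig.TrainConfig(epochs=2, scheduler_period=2, batch_size=16)
        model, _ = ig.train_model(model, tiny_task["ds"],
                                  tiny_task["graphs"], tiny_task["split"],
                                  cfg, seed=0)
        frame = tiny_task["ds"].frame
        part = frame["record_id"].map(
            tiny_task["split"].record_partition)
        train_temps = frame.loc[part == "train", "temperature_K"]
        assert model.cond_mean[0] == pytest.approx(train_temps.mean())

    def test_log10_target_transform_round_trips_metrics(self, tiny_task,
                                                        small_cfg):
        model = ig.build_model(small_cfg, seed=1)
        cfg = ig.TrainConfig(epochs=4, scheduler_period=4, batch_size=16,
                             target_transform="log10")
        _, metrics = ig.train_model(model, tiny_task["ds"],
                                    tiny_task["graphs"],
                                    tiny_task["split"], cfg, seed=1)
        # metrics are reported on the original property scale
        assert metrics["test"]["rmse"] < 100.0
        assert metrics["test"]["mare"] >= 0.0


class TestAggregateRuns:
    def test_two_seeds_by_two_reps(self, tiny_task, small_cfg):
        cfg = ig.TrainConfig(epochs=3, scheduler_period=3, batch_size=16,
                             n_seeds=2, n_reps=2)

        def policy(seed):
            return ig.assign_splits(tiny_task["ds"],
                                    tiny_task["test_ils"], seed=seed)
        summary, runs = ig.aggregate_runs(small_cfg, cfg, tiny_task["ds"],
                                          tiny_task["graphs"], policy)
        assert len(runs) == 4
        for split in ("train", "val", "test"):
            for metric in ("r2", "rmse", "mare"):
                cell = summary[split][metric]
                assert np.isfinite(cell["mean"])
                assert cell["std"] >= 0.0

    def test_repetitions_differ_through_initialization(self, tiny_task,
                                                       small_cfg):
        cfg = ig.TrainConfig(epochs=3, scheduler_period=3, batch_size=16,
                             n_seeds=1, n_reps=2)

        def policy(seed):
            return ig.assign_splits(tiny_task["ds"],
                                    tiny_task["test_ils"], seed=seed)
        _, runs = ig.aggregate_runs(small_cfg, cfg, tiny_task["ds"],
                                    tiny_task["graphs"], policy)
        assert not np.array_equal(runs[0].loss_curve, runs[1].loss_curve)


class TestTransfer:
    @pytest.fixture()
    def pretrained(self, tiny_task, small_cfg):
        model = ig.build_model(small_cfg, seed=2)
        cfg = ig.TrainConfig(epochs=2, scheduler_period=2, batch_size=16)
        model, _ = ig.train_model(model, tiny_task["ds"],
                                  tiny_task["graphs"], tiny_task["split"],
                                  cfg, seed=2)
        return model

    def test_linear_only_freezes_conv_weights_bitwise(self, tiny_task,
                                                      pretrained):
        before = [p.data.copy() for p in pretrained.conv_parameters()]
        cfg = ig.TrainConfig(epochs=2, scheduler_period=2, batch_size=16)
        model, _ = ig.transfer_weights(pretrained, tiny_task["ds"],
                                       tiny_task["graphs"],
                                       tiny_task["split"], "linear_only",
                                       cfg, seed=3)
        for b, p in zip(before, model.conv_parameters()):
            assert np.array_equal(b, p.data)

    def test_fine_tune_updates_conv_weights(self, tiny_task, pretrained):
        before = [p.data.copy() for p in pretrained.conv_parameters()]
        cfg = ig.TrainConfig(epochs=2, scheduler_period=2, batch_size=16)
        model, _ = ig.transfer_weights(pretrained, tiny_task["ds"],
                                       tiny_task["graphs"],
                                       tiny_task["split"], "fine_tune",
                                       cfg, seed=3)
        changed = any(not np.array_equal(b, p.data)
                      for b, p in zip(before, model.conv_parameters()))
        assert changed

    def test_head_reinitialized_when_condition_count_changes(
            self, pretrained):
        target = initialize_from(pretrained, n_conditions=2)
        assert target.config.n_conditions == 2
        for p_src, p_dst in zip(pretrained.conv_parameters(),
                                target.conv_parameters()):
            assert np.array_equal(p_src.data, p_dst.data)
        assert (target.head[0].W.data.shape[0]
                == pretrained.head[0].W.data.shape[0] + 1)

    def test_unknown_mode_rejected(self, tiny_task, pretrained):
        with pytest.raises(TransferError):
            ig.transfer_weights(pretrained, tiny_task["ds"],
                                tiny_task["graphs"], tiny_task["split"],
                                "feature_extraction")
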