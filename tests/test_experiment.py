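"""Study orchestration: factor grids, shared test sets, resumability."""

import json

import pandas as pd
import pytest
from click.testing import CliRunner

import iongraph as ig
from iongraph.cli import main as cli_main
from iongraph.errors import ConfigError, ReportError
from iongraph.experiment import (StudyConfig, read_report, run_study,
                                 write_report)


def small_study(tmp_path, axes, **overrides):
    return StudyConfig(
        synthetic=ig.SyntheticSpec(n_cations=5, n_anions=4, noise_sd=0.05,
                                   temps=(288.15, 308.15, 328.15),
                                   mislabel_fraction=0.05, seed=11),
        axes=axes,
        model=ig.ModelConfig(conv_widths=(8, 16, 16, 8),
                             head_widths=(16, 8)),
        train=ig.TrainConfig(epochs=2, scheduler_period=2, batch_size=16,
                             n_seeds=1, n_reps=2),
        out_dir=str(tmp_path / "study"),
        seed=1,
        **overrides)


@pytest.fixture(scope="module")
def grid_result(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("study")
    cfg = small_study(tmp, {"dataset_variant": ["clean", "raw"],
                            "detection_method": ["none", "mad"]})
    return cfg, run_study(cfg)


class TestRunStudy:
    def test_factor_grid_yields_one_row_per_combination(self,
                                                        grid_result):
        _, table = grid_result
        assert len(table) == 4
        assert "error" not in table.columns
        assert {"test_r2_mean", "test_r2_std"} <= set(table.columns)

    def test_clean_and_raw_cells_share_the_test_ils(self, grid_result):
        _, table = grid_result
        assert table["test_ils"].map(tuple).nunique() == 1

    def test_rerun_resumes_to_an_identical_table(self, grid_result):
        cfg, table = grid_result
        again = run_study(cfg)
        pd.testing.assert_frame_equal(
            table.drop(columns="test_ils"),
            again.drop(columns="test_ils"))

    def test_mad_cell_removes_some_raw_records(self, grid_result):
        _, table = grid_result
        raw_mad = table[(table.dataset_variant == "raw")
                        & (table.detection_method == "mad")]
        assert raw_mad["fraction_removed"].iloc[0] > 0.0

    def test_unknown_axis_rejected(self, tmp_path):
        with pytest.raises(ConfigError):
            small_study(tmp_path, {"engine_type": ["rdkit"]})

    def test_empty_axes_rejected(self, tmp_path):
        with pytest.raises(ConfigError):
            small_study(tmp_path, {})

    def test_sequential_mode_stages_one_axis_at_a_time(self, tmp_path):
        cfg = small_study(
            tmp_path, {"detection_method": ["none", "mad"],
                       "ionic_bond": [True, False]},
            sequential=True,
            winners={"detection_method": "mad"})
        table = run_study(cfg)
        assert len(table) == 4
        staged = table[table["_stage"] == "ionic_bond"]
        assert set(staged["detection_method"]) == {"mad"}


class TestReports:
    @pytest.fixture()
    def table(self):
        return pd.DataFrame([
            {"scenario": "a", "test_r2_mean": 0.9, "test_r2_std": 0.01},
            {"scenario": "b", "test_r2_mean": 0.8, "test_r2_std": 0.02}])

    def test_json_csv_round_trip_is_lossless(self, tmp_path, table):
        write_report(table, "json", tmp_path / "r.json")
        via_json = read_report("json", tmp_path / "r.json")
        write_report(via_json, "csv", tmp_path / "r.csv")
        via_csv = read_report("csv", tmp_path / "r.csv")
        pd.testing.assert_frame_equal(table, via_csv, check_like=True)

    def test_markdown_has_header_plus_one_row_per_combination(
            self, tmp_path, table):
        write_report(table, "markdown", tmp_path / "r.md")
        lines = [l for l in (tmp_path / "r.md").read_text().splitlines()
                 if l.strip()]
        assert len(lines) == 2 + len(table)   # header, rule, rows

    def test_empty_table_is_an_error_not_an_empty_file(self, tmp_path):
        with pytest.raises(ReportError):
            write_report(pd.DataFrame(), "csv", tmp_path / "empty.csv")
        assert not (tmp_path / "empty.csv").exists()


class TestCli:
    def test_synth_then_curate_round_trip(self, tmp_path):
        runner = CliRunner()
        spec = tmp_path / "spec.yaml"
        spec.write_text("n_cations: 4\nn_anions: 3\n"
                        "mislabel_fraction: 0.05\n")
        data = tmp_path / "data.csv"
        result = runner.invoke(cli_main, ["synth", "--spec", str(spec),
                                          "--seed", "3", "--out",
                                          str(data)])
        assert result.exit_code == 0, result.output
        ds = ig.PropertyDataset.from_csv(data)
        assert len(ds) == 4 * 3 * 8

        out = tmp_path / "curated.csv"
        report = tmp_path / "report.json"
        result = runner.invoke(cli_main, [
            "curate", "--method", "mad", str(data), str(out),
            "--report", str(report)])
        assert result.exit_code == 0, result.output
        payload = json.loads(report.read_text())
        assert payload["method"] == "mad"
        assert len(ig.PropertyDataset.from_csv(out)) <= len(ds)

    def test_train_then_transfer_commands(self, tmp_path):
        runner = CliRunner()
        spec = tmp_path / "spec.yaml"
        spec.write_text("n_cations: 4\nn_anions: 3\n"
                        "temps: [288.15, 308.15, 328.15]\n")
        data = tmp_path / "data.csv"
        splits = tmp_path / "splits.json"
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "model:\n  conv_widths: [8, 16, 16, 8]\n"
            "  head_widths: [16, 8]\n"
            "train:\n  epochs: 2\n  scheduler_period: 2\n"
            "  batch_size: 16\n")
        for args in (["synth", "--spec", str(spec), "--seed", "1",
                      "--out", str(data)],
                     ["split", "--seed", "1", str(data), "--out",
                      str(splits)],
                     ["train", "--config", str(cfg), "--seed", "1",
                      str(data), str(splits), "--out",
                      str(tmp_path / "run")],
                     ["transfer", "--mode", "linear_only", "--pretrained",
                      str(tmp_path / "run" / "model.npz"), "--config",
                      str(cfg), str(data), str(splits), "--out",
                      str(tmp_path / "transfer_run")]):
            result = runner.invoke(cli_main, args)
            assert result.exit_code == 0, (args[0], result.output)
        assert (tmp_path / "transfer_run" / "model.npz").exists()

    def test_split_command_writes_partition(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data.csv"
        runner.invoke(cli_main, ["synth", "--seed", "1", "--out",
                                 str(data)])
        out = tmp_path / "splits.json"
        result = runner.invoke(cli_main, [
            "split", "--mode", "random", "--seed", "2",
            str(data), "--out", str(out)])
        assert result.exit_code == 0, result.output
        payload = json.loads(out.read_text())
        counts = pd.Series(payload["clean"]).value_counts(normalize=True)
        assert counts["train"] == pytest.approx(0.75, abs=0.03)
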