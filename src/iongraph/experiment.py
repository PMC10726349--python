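"""Orchestration of comparative studies over pipeline factors.

A study sweeps a factor grid — dataset variant (clean/raw), outlier
detection method, charge scheme, graph scenario, virtual-ionic-bond
on/off, convolution type, transfer mode — training the model for every
combination and reporting mean ± std of R²/RMSE/MARE per split.  The test
ILs are selected once from the clean records and shared by every cell, so
clean and raw variants are always scored on the same held-out liquids.
Completed cells are persisted as JSON and skipped on rerun.
"""

from __future__ import annotations

import itertools
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import curate_dataset
from .data import PropertyDataset
from .errors import ConfigError, ReportError
from .model import ModelConfig
from .pipeline import GraphFeaturizer, featurize_dataset
from .splitting import assign_splits, select_test_ils
from .synthetic import SyntheticSpec, generate_ion_library, \
    synthesize_dataset
from .training import (TrainConfig, aggregate_runs, build_model,
                       train_model, transfer_weights)

logger = logging.getLogger(__name__)

FACTOR_DEFAULTS = {
    "dataset_variant": "raw",
    "detection_method": "none",
    "charge_scheme": "formal",
    "scenario": "a",
    "ionic_bond": True,
    "conv_type": "gcn",
    "split_mode": "random",
    "transfer_mode": "none",
}
METRICS = ("r2", "rmse", "mare")
SPLITS = ("train", "val", "test")


@dataclass
class StudyConfig:
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    axes: dict = field(default_factory=dict)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    engine: str = "rdkit"
    pooling_mode: str = "separate"
    test_fraction: float = 0.10
    seed: int = 0
    out_dir: str | None = None
    pretrain_synthetic: SyntheticSpec | None = None
    sequential: bool = False
    winners: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.axes) - set(FACTOR_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown study axes: {sorted(unknown)}")
        if not any(self.axes.values()):
            raise ConfigError("at least one study axis must be non-empty")


def _combinations(cfg: StudyConfig):
    axes = {k: v for k, v in cfg.axes.items() if v}
    if cfg.sequential:
        # staged protocol: vary one axis at a time, carrying configured
        # winners forward and defaults for axes not yet staged
        for axis, levels in axes.items():
            for level in levels:
                combo = dict(FACTOR_DEFAULTS)
                combo.update({k: cfg.winners[k] for k in axes
                              if k in cfg.winners and k != axis})
                combo[axis] = level
                combo["_stage"] = axis
                yield combo
        return
    names = list(axes)
    n_cells = 1
    for levels in axes.values():
        n_cells *= len(levels)
    if n_cells > 64:
        logger.warning("factor grid has %d combinations", n_cells)
    for values in itertools.product(*axes.values()):
        combo = dict(FACTOR_DEFAULTS)
        combo.update(dict(zip(names, values)))
        yield combo


def _slug(combo: dict) -> str:
    text = "_".join(f"{k}-{v}" for k, v in sorted(combo.items()))
    return re.sub(r"[^A-Za-z0-9_.-]", "", text)


def _model_for(cfg: StudyConfig, combo: dict) -> ModelConfig:
    scenario = combo["scenario"]
    return ModelConfig(
        conv_type=combo["conv_type"],
        conv_widths=cfg.model.conv_widths,
        head_widths=cfg.model.head_widths,
        n_conditions=cfg.model.n_conditions,
        dropout_rate=cfg.model.dropout_rate,
        scenario=scenario,
        pooling_mode=cfg.pooling_mode if scenario == "c" else None,
        share_towers=cfg.model.share_towers,
        mfc_max_degree=cfg.model.mfc_max_degree,
    )


def _cell_dataset(full: PropertyDataset, combo: dict, test_ils: set):
    variant = (full.clean_subset() if combo["dataset_variant"] == "clean"
               else full)
    is_test = variant.frame["il_id"].isin(test_ils).to_numpy()
    nontest = variant.drop_mask(is_test)
    curated, report = curate_dataset(nontest, combo["detection_method"])
    test_part = variant.frame[is_test]
    frame = pd.concat([curated.frame, test_part], ignore_index=True)
    return PropertyDataset.from_frame(frame), report


def run_study(cfg: StudyConfig) -> pd.DataFrame:
    """Execute every factor combination; returns the results table."""
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        (out_dir / "cells").mkdir(parents=True, exist_ok=True)

    pairs = generate_ion_library(cfg.synthetic.n_cations,
                                 cfg.synthetic.n_anions, cfg.synthetic.seed)
    full = synthesize_dataset(pairs, cfg.synthetic)
    test_ils = select_test_ils(full.clean_subset(), cfg.test_fraction,
                               seed=cfg.seed)

    pretrained = {}
    featurizer_cache = {}
    rows = []
    for combo in _combinations(cfg):
        slug = _slug(combo)
        cell_path = out_dir / "cells" / f"{slug}.json" if out_dir else None
        if cell_path and cell_path.exists():
            rows.append(json.loads(cell_path.read_text()))
            continue
        row = dict(combo)
        try:
            row.update(_run_cell(cfg, combo, full, test_ils,
                                 featurizer_cache, pretrained))
        except Exception as exc:   # noqa: BLE001 - recorded in-row
            logger.exception("cell %s failed", slug)
            row["error"] = str(exc)
        rows.append(row)
        if cell_path:
            cell_path.write_text(json.dumps(row))
    table = pd.DataFrame(rows)
    axis_cols = [c for c in FACTOR_DEFAULTS if c in table.columns]
    table = table.sort_values(axis_cols).reset_index(drop=True)
    if out_dir:
        table.to_csv(out_dir / "results.csv", index=False)
    return table


def _featurizer_for(cfg, combo, cache) -> GraphFeaturizer:
    key = (combo["scenario"], combo["charge_scheme"], combo["ionic_bond"])
    if key not in cache:
        cache[key] = GraphFeaturizer(
            scenario=combo["scenario"], engine=cfg.engine,
            charge_scheme=combo["charge_scheme"],
            ionic_bond=combo["ionic_bond"] and combo["scenario"] != "c",
            pooling_mode=cfg.pooling_mode)
    return cache[key]


def _run_cell(cfg, combo, full, test_ils, featurizer_cache, pretrained):
    ds, report = _cell_dataset(full, combo, test_ils)
    featurizer = _featurizer_for(cfg, combo, featurizer_cache)
    graphs = featurize_dataset(ds, featurizer, skip_failures=False)
    model_cfg = _model_for(cfg, combo)

    def split_policy(seed):
        return assign_splits(ds, test_ils, mode=combo["split_mode"],
                             seed=seed)

    if combo["transfer_mode"] == "none":
        summary, _ = aggregate_runs(model_cfg, cfg.train, ds, graphs,
                                    split_policy, base_seed=cfg.seed)
    else:
        summary = _transfer_cell(cfg, combo, model_cfg, ds, graphs,
                                 split_policy, featurizer, pretrained)
    out = {"n_records": len(ds),
           "fraction_removed": report.fraction_removed,
           "test_ils": sorted(map(str, test_ils))}
    for split in summary:
        for metric in METRICS:
            out[f"{split}_{metric}_mean"] = summary[split][metric]["mean"]
            out[f"{split}_{metric}_std"] = summary[split][metric]["std"]
    return out


def _transfer_cell(cfg, combo, model_cfg, ds, graphs, split_policy,
                   featurizer, pretrained):
    if cfg.pretrain_synthetic is None:
        raise ConfigError(
            "transfer-mode cells need a pretraining dataset spec")
    key = (combo["scenario"], combo["conv_type"], combo["charge_scheme"],
           combo["ionic_bond"])
    if key not in pretrained:
        pre_pairs = generate_ion_library(cfg.pretrain_synthetic.n_cations,
                                         cfg.pretrain_synthetic.n_anions,
                                         cfg.pretrain_synthetic.seed)
        pre_ds = synthesize_dataset(pre_pairs, cfg.pretrain_synthetic)
        pre_graphs = featurize_dataset(pre_ds, featurizer)
        pre_test = select_test_ils(pre_ds.clean_subset(),
                                   cfg.test_fraction, seed=cfg.seed)
        pre_split = assign_splits(pre_ds, pre_test, seed=cfg.seed)
        model = build_model(model_cfg, seed=cfg.seed)
        model, _ = train_model(model, pre_ds, pre_graphs, pre_split,
                               cfg.train, seed=cfg.seed)
        pretrained[key] = model
    metric_runs = []
    for s in range(cfg.train.n_seeds):
        split = split_policy(cfg.seed + s)
        _, metrics = transfer_weights(pretrained[key], ds, graphs, split,
                                      combo["transfer_mode"], cfg.train,
                                      seed=cfg.seed + s)
        metric_runs.append(metrics)
    summary = {}
    for split_name in metric_runs[0].metrics:
        summary[split_name] = {}
        for metric in METRICS:
            values = np.array([m[split_name][metric]
                               for m in metric_runs])
            summary[split_name][metric] = {
                "mean": float(values.mean()),
                "std": (float(values.std(ddof=1)) if len(values) > 1
                        else 0.0)}
    return summary


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def write_report(table: pd.DataFrame, fmt: str, path) -> None:
    """Render the study results table as csv, json, or markdown."""
    if table is None or len(table) == 0:
        raise ReportError("refusing to write an empty results table")
    path = Path(path)
    if fmt == "csv":
        table.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(table.to_json(orient="records", indent=2))
    elif fmt == "markdown":
        path.write_text(table.to_markdown(index=False))
    else:
        raise ReportError(f"unknown report format '{fmt}'")


def read_report(fmt: str, path) -> pd.DataFrame:
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "json":
        return pd.read_json(path, orient="records")
    raise ReportError(f"cannot read report format '{fmt}'")
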