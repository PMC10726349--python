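"""End-to-end benchmark protocols on synthetic data with known truth.

These encode the package's reference study conditions:

* :func:`parameter_recovery` — can the default network recover a noiseless
  linear-in-descriptors property map from graphs alone?  (300 ILs × 8
  temperatures, scenario A + virtual ionic bond + formal charges, GCN.)
* :func:`mislabel_robustness` — how much does held-out accuracy degrade
  when a fraction of *training* records is grossly mislabeled
  (multiplied or divided by a large factor), mirroring raw literature
  data?  Run at reduced scale over several seeds.
* :func:`transfer_contract` — parameter-freezing contracts of the two
  transfer modes on a short synthetic run.
"""

from __future__ import annotations

import numpy as np

from .data import PropertyDataset
from .model import ModelConfig, build_model
from .pipeline import GraphFeaturizer, featurize_dataset
from .splitting import assign_splits, select_test_ils
from .synthetic import SyntheticSpec, generate_ion_library, \
    synthesize_dataset
from .training import TrainConfig, train_model, transfer_weights


def _build_task(spec: SyntheticSpec, featurizer: GraphFeaturizer,
                split_seed: int, split_mode: str = "random"):
    pairs = generate_ion_library(spec.n_cations, spec.n_anions, spec.seed)
    ds = synthesize_dataset(pairs, spec)
    graphs = featurize_dataset(ds, featurizer)
    test_ils = select_test_ils(ds.clean_subset(), 0.10, seed=split_seed)
    split = assign_splits(ds, test_ils, mode=split_mode, seed=split_seed)
    return ds, graphs, split


def parameter_recovery(seed: int = 0, n_cations: int = 30,
                       n_anions: int = 10, epochs: int = 100,
                       conv_widths=(128, 256, 256, 128),
                       head_widths=(256, 128)) -> dict:
    """Train the default GCN on a noiseless synthetic dataset; report R²."""
    spec = SyntheticSpec(n_cations=n_cations, n_anions=n_anions,
                         noise_sd=0.0, seed=seed)
    featurizer = GraphFeaturizer(scenario="a", charge_scheme="formal",
                                 ionic_bond=True)
    ds, graphs, split = _build_task(spec, featurizer, split_seed=seed)
    model = build_model(ModelConfig(conv_widths=tuple(conv_widths),
                                    head_widths=tuple(head_widths)),
                        seed=seed)
    cfg = TrainConfig(epochs=epochs, scheduler_period=min(40, epochs))
    model, metrics = train_model(model, ds, graphs, split, cfg, seed=seed)
    return {"n_records": len(ds), "split_counts": split.counts(),
            "metrics": metrics.metrics,
            "loss_curve": metrics.loss_curve}


def _corrupt_train_records(ds: PropertyDataset, split, fraction: float,
                           scale: float, seed: int) -> PropertyDataset:
    """Multiply-or-divide corruption applied to the training split only."""
    rng = np.random.default_rng(seed)
    frame = ds.frame.copy()
    part = frame["record_id"].map(split.record_partition)
    train_idx = frame.index[part == "train"].to_numpy()
    n_corrupt = int(round(fraction * len(train_idx)))
    chosen = rng.choice(train_idx, size=n_corrupt, replace=False)
    factors = np.where(rng.random(n_corrupt) < 0.5, scale, 1.0 / scale)
    frame.loc[chosen, "value"] *= factors
    frame.loc[chosen, "quality"] = "raw"
    return PropertyDataset(frame)


def mislabel_robustness(seed: int = 0, n_seeds: int = 5,
                        fraction: float = 0.10, scale: float = 10.0,
                        n_cations: int = 10, n_anions: int = 8,
                        n_temps: int = 6, epochs: int = 100,
                        conv_widths=(32, 64, 64, 32),
                        head_widths=(64, 32)) -> dict:
    """Clean-trained vs mislabel-trained test R², per seed and median."""
    temps = tuple(283.15 + 12.0 * k for k in range(n_temps))
    results = {"clean_r2": [], "corrupt_r2": [], "degradation": [],
               "curated_r2": [], "curated_degradation": []}
    featurizer = GraphFeaturizer(scenario="a", charge_scheme="formal",
                                 ionic_bond=True)
    for k in range(n_seeds):
        run_seed = seed + k
        spec = SyntheticSpec(n_cations=n_cations, n_anions=n_anions,
                             temps=temps, noise_sd=0.0, seed=run_seed)
        ds, graphs, split = _build_task(spec, featurizer,
                                        split_seed=run_seed)
        cfg = TrainConfig(epochs=epochs,
                          scheduler_period=min(40, epochs))
        model_cfg = ModelConfig(conv_widths=tuple(conv_widths),
                                head_widths=tuple(head_widths))
        clean_model = build_model(model_cfg, seed=run_seed)
        _, clean_metrics = train_model(clean_model, ds, graphs, split,
                                       cfg, seed=run_seed)
        corrupted = _corrupt_train_records(ds, split, fraction, scale,
                                           seed=run_seed + 1000)
        corrupt_model = build_model(model_cfg, seed=run_seed)
        _, corrupt_metrics = train_model(corrupt_model, corrupted, graphs,
                                         split, cfg, seed=run_seed)
        # the pipeline's curation path: MAD filtering of the corrupted
        # training records before fitting
        cur_ds, cur_split = _curate_training(corrupted, split)
        curated_model = build_model(model_cfg, seed=run_seed)
        _, curated_metrics = train_model(curated_model, cur_ds, graphs,
                                         cur_split, cfg, seed=run_seed)

        r2c = clean_metrics["test"]["r2"]
        r2m = corrupt_metrics["test"]["r2"]
        r2k = curated_metrics["test"]["r2"]
        results["clean_r2"].append(r2c)
        results["corrupt_r2"].append(r2m)
        results["degradation"].append(r2c - r2m)
        results["curated_r2"].append(r2k)
        results["curated_degradation"].append(r2c - r2k)
    for key in ("degradation", "clean_r2", "corrupt_r2", "curated_r2",
                "curated_degradation"):
        results[f"median_{key}"] = float(np.median(results[key]))
    return results


def _curate_training(ds: PropertyDataset, split):
    """Drop MAD-flagged training records; keep val/test untouched."""
    from dataclasses import replace as dc_replace

    from .curation import detect_outliers

    frame = ds.frame
    part = frame["record_id"].map(split.record_partition)
    train_mask = (part == "train").to_numpy()
    flags = detect_outliers(frame.loc[train_mask, "value"].to_numpy(),
                            "mad", 3.0)
    drop_ids = set(frame.loc[train_mask, "record_id"].to_numpy()[flags])
    kept = PropertyDataset(
        frame[~frame["record_id"].isin(drop_ids)].reset_index(drop=True))
    partition = {rid: p for rid, p in split.record_partition.items()
                 if rid not in drop_ids}
    return kept, dc_replace(split, record_partition=partition)


def transfer_contract(seed: int = 0, epochs: int = 2) -> dict:
    """Max |Δweight| of the conv stack under each transfer mode."""
    spec = SyntheticSpec(n_cations=6, n_anions=4, noise_sd=0.05,
                         temps=(288.15, 308.15, 328.15), seed=seed)
    featurizer = GraphFeaturizer(scenario="a", charge_scheme="formal",
                                 ionic_bond=True)
    ds, graphs, split = _build_task(spec, featurizer, split_seed=seed)
    model_cfg = ModelConfig(conv_widths=(16, 32, 32, 16),
                            head_widths=(32, 16))
    cfg = TrainConfig(epochs=epochs, scheduler_period=epochs,
                      batch_size=32)
    pretrained = build_model(model_cfg, seed=seed)
    pretrained, _ = train_model(pretrained, ds, graphs, split, cfg,
                                seed=seed)
    out = {}
    for mode in ("linear_only", "fine_tune"):
        before = [p.data.copy() for p in pretrained.conv_parameters()]
        model, _ = transfer_weights(pretrained, ds, graphs, split, mode,
                                    cfg, seed=seed + 1)
        deltas = [np.abs(b - p.data).max()
                  for b, p in zip(before, model.conv_parameters())]
        out[mode] = float(max(deltas))
    return out
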