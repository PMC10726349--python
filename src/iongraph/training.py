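"""Training loop, metrics, repeated-run aggregation, transfer learning.

Training minimizes mean squared error with Adam (lr 0.001) under a
cosine-annealing schedule restarting every 40 epochs, for 300 epochs by
default; targets and conditions are z-scored with training-split
statistics (stored on the model), and the reported model is the
best-validation-RMSE checkpoint.  Runs are aggregated over ``n_seeds``
split seeds × ``n_reps`` re-initializations, reported as mean ± sample
standard deviation per metric per split.

Transfer modes: ``fine_tune`` updates all weights starting from the
pretrained values; ``linear_only`` freezes the convolution towers and
retrains the fully connected head only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .data import PropertyDataset
from .errors import ConfigError, TrainingError, TransferError
from .model import (GNNRegressor, ModelConfig, batch_inputs, build_model)
from .nn import Adam, CosineAnnealingWarmRestarts
from .splitting import SplitAssignment

logger = logging.getLogger(__name__)

TARGET_TRANSFORMS = ("identity", "log10")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001
    epochs: int = 300
    scheduler_period: int = 40
    batch_size: int = 64
    n_seeds: int = 4
    n_reps: int = 10
    target_transform: str = "identity"

    def __post_init__(self):
        if min(self.lr, self.epochs, self.scheduler_period,
               self.batch_size, self.n_seeds, self.n_reps) <= 0:
            raise ConfigError("all training settings must be positive")
        if self.epochs < self.scheduler_period:
            raise ConfigError("epochs must be >= scheduler period")
        if self.target_transform not in TARGET_TRANSFORMS:
            raise ConfigError(
                f"unknown target transform '{self.target_transform}'")


@dataclass
class RunMetrics:
    metrics: dict                  # split -> {"r2","rmse","mare"}
    loss_curve: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __getitem__(self, split):
        return self.metrics[split]


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray):
    """(R², RMSE, MARE) for a prediction vector.

    R² = 1 − SSres/SStot; RMSE = √(mean squared error); MARE =
    mean(|ŷ−y| / |y|).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ConfigError("metric inputs must be equal-length, size >= 2")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ConfigError("R² undefined for zero-variance targets")
    if np.any(y_true == 0.0):
        raise ConfigError("MARE undefined when a true value is zero")
    ss_res = float(((y_true - y_pred) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    mare = float(np.mean(np.abs(y_pred - y_true) / np.abs(y_true)))
    return r2, rmse, mare


# ---------------------------------------------------------------------------
# data marshalling
# ---------------------------------------------------------------------------

def _split_rows(ds: PropertyDataset, split: SplitAssignment) -> dict:
    part = ds.frame["record_id"].map(split.record_partition)
    if part.isna().any():
        raise TrainingError("split does not cover every record")
    return {name: np.flatnonzero((part == name).to_numpy())
            for name in ("train", "val", "test")}


class _Arrays:
    """Per-record model inputs resolved once before the epoch loop."""

    def __init__(self, ds: PropertyDataset, graphs: dict,
                 n_conditions: int):
        frame = ds.frame
        missing = set(frame["il_id"]) - set(graphs)
        if missing:
            raise TrainingError(
                f"no graph for ILs: {sorted(missing)[:5]}")
        self.items = [graphs[il] for il in frame["il_id"]]
        self.cond = ds.conditions(n_conditions)
        if not np.all(np.isfinite(self.cond)):
            raise TrainingError(
                "non-finite measurement conditions (is pressure present?)")
        self.y = ds.values


def _transform(y, kind):
    if kind == "identity":
        return y
    if np.any(y <= 0):
        raise TrainingError("log10 target transform needs positive values")
    return np.log10(y)


def _untransform(y, kind):
    return y if kind == "identity" else 10.0 ** y


def _predict_rows(model, arrays, rows, chunk=1024) -> np.ndarray:
    """Standardized-scale predictions for dataset rows (eval mode)."""
    out = np.empty(len(rows))
    cond_std = model.standardize_conditions(arrays.cond[rows])
    for lo in range(0, len(rows), chunk):
        sel = rows[lo:lo + chunk]
        batch = batch_inputs([arrays.items[i] for i in sel])
        out[lo:lo + chunk] = model.forward(
            batch, cond_std[lo:lo + chunk], training=False).data[:, 0]
    return out


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

def train_model(model: GNNRegressor, ds: PropertyDataset, graphs: dict,
                split: SplitAssignment, cfg: TrainConfig = TrainConfig(),
                seed: int = 0, trainable: str = "all"):
    """Fit `model` on the train split; returns (model, RunMetrics).

    The model is left holding the parameters of the epoch with the best
    validation RMSE.  ``trainable`` restricts the optimized parameters
    ("all" or "head", the latter for transfer learning).
    """
    rows = _split_rows(ds, split)
    if rows["train"].size == 0 or rows["val"].size == 0:
        raise TrainingError("empty train or validation split")
    arrays = _Arrays(ds, graphs, model.config.n_conditions)

    y_t = _transform(arrays.y, cfg.target_transform)
    train_rows = rows["train"]
    model.cond_mean = arrays.cond[train_rows].mean(axis=0)
    model.cond_std = arrays.cond[train_rows].std(axis=0)
    model.cond_std[model.cond_std == 0.0] = 1.0
    model.y_mean = float(y_t[train_rows].mean())
    model.y_std = float(y_t[train_rows].std()) or 1.0
    cond_std = (arrays.cond - model.cond_mean) / model.cond_std
    y_std = (y_t - model.y_mean) / model.y_std

    if trainable == "all":
        params = model.parameters()
    elif trainable == "head":
        params = model.head_parameters()
    else:
        raise ConfigError(f"unknown trainable selection '{trainable}'")
    optimizer = Adam(params, lr=cfg.lr)
    scheduler = CosineAnnealingWarmRestarts(optimizer, cfg.scheduler_period)
    rng = np.random.default_rng(seed)

    best_val, best_state = np.inf, None
    loss_curve = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        scheduler.step(epoch)
        order = rng.permutation(train_rows)
        epoch_losses = []
        for lo in range(0, len(order), cfg.batch_size):
            sel = order[lo:lo + cfg.batch_size]
            if sel.size < 2:
                continue    # batch-norm needs >= 2 rows
            batch = batch_inputs([arrays.items[i] for i in sel])
            pred = model.forward(batch, cond_std[sel], training=True,
                                 rng=rng)
            resid = pred - y_std[sel][:, None]
            loss = (resid * resid).mean()
            if not np.isfinite(loss.data):
                raise TrainingError(
                    f"training diverged at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        loss_curve[epoch] = float(np.mean(epoch_losses))
        val_pred = _predict_rows(model, arrays, rows["val"])
        val_rmse = float(np.sqrt(np.mean(
            (val_pred - y_std[rows["val"]]) ** 2)))
        if val_rmse < best_val:
            best_val = val_rmse
            best_state = {k: v.copy()
                          for k, v in model.state_arrays().items()}

    if best_state is not None:
        model.load_state_arrays(best_state)

    metrics = {}
    for name, sel in rows.items():
        if sel.size < 2:
            continue
        pred_std = _predict_rows(model, arrays, sel)
        pred = _untransform(pred_std * model.y_std + model.y_mean,
                            cfg.target_transform)
        r2, rmse, mare = compute_metrics(arrays.y[sel], pred)
        metrics[name] = {"r2": r2, "rmse": rmse, "mare": mare}
    return model, RunMetrics(metrics=metrics, loss_curve=loss_curve)


# ---------------------------------------------------------------------------
# repeated runs
# ---------------------------------------------------------------------------

def aggregate_runs(model_config: ModelConfig, cfg: TrainConfig,
                   ds: PropertyDataset, graphs: dict, split_policy,
                   base_seed: int = 0):
    """mean ± std of each metric over n_seeds × n_reps runs.

    ``split_policy(seed)`` must return a SplitAssignment.  The seed varies
    both the split and the initialization; repetitions re-draw the
    initialization only.  Returns (summary, runs) where summary is
    {split: {metric: {"mean": .., "std": ..}}}.
    """
    if cfg.n_seeds * cfg.n_reps < 2:
        raise ConfigError("aggregation needs at least 2 runs")
    runs, failures = [], []
    for s in range(cfg.n_seeds):
        split_seed = base_seed + s
        split = split_policy(split_seed)
        for r in range(cfg.n_reps):
            init_seed = (base_seed * 100_000 + s * 1_000 + r) % (2 ** 31)
            try:
                model = build_model(model_config, seed=init_seed)
                _, metrics = train_model(model, ds, graphs, split, cfg,
                                         seed=split_seed)
                runs.append(metrics)
            except Exception as exc:   # noqa: BLE001 - collected below
                failures.append((s, r, str(exc)))
    if failures:
        raise TrainingError(f"runs failed: {failures}")
    summary = {}
    for split_name in runs[0].metrics:
        summary[split_name] = {}
        for metric in ("r2", "rmse", "mare"):
            values = np.array([run[split_name][metric] for run in runs])
            summary[split_name][metric] = {
                "mean": float(values.mean()),
                "std": float(values.std(ddof=1)) if len(values) > 1
                else 0.0,
            }
    return summary, runs


# ---------------------------------------------------------------------------
# transfer learning
# ---------------------------------------------------------------------------

TRANSFER_MODES = ("fine_tune", "linear_only")


def initialize_from(pretrained: GNNRegressor,
                    n_conditions: int | None = None) -> GNNRegressor:
    """A fresh model warm-started from `pretrained`.

    Convolution weights are always copied; the head is copied when the
    condition count matches and re-initialized (seeded) otherwise.
    """
    n_conditions = (pretrained.config.n_conditions
                    if n_conditions is None else n_conditions)
    config = dc_replace(pretrained.config, n_conditions=n_conditions)
    target = build_model(config, seed=1)
    for p_src, p_dst in zip(pretrained.conv_parameters(),
                            target.conv_parameters()):
        p_dst.data = p_src.data.copy()
    if n_conditions == pretrained.config.n_conditions:
        for p_src, p_dst in zip(pretrained.head_parameters(),
                                target.head_parameters()):
            p_dst.data = p_src.data.copy()
        target.batch_norm.running_mean = (
            pretrained.batch_norm.running_mean.copy())
        target.batch_norm.running_var = (
            pretrained.batch_norm.running_var.copy())
    return target


def transfer_weights(pretrained: GNNRegressor, ds: PropertyDataset,
                     graphs: dict, split: SplitAssignment, mode: str,
                     cfg: TrainConfig = TrainConfig(), seed: int = 0):
    """Retrain a pretrained model on a new property dataset.

    ``linear_only`` leaves the convolution parameters bitwise unchanged;
    ``fine_tune`` updates everything from the pretrained starting point.
    Returns (model, RunMetrics).
    """
    if mode not in TRANSFER_MODES:
        raise TransferError(f"unknown transfer mode '{mode}'")
    sample = next(iter(graphs.values()))
    scenario_ok = (
        (pretrained.config.scenario == "c")
        == (not hasattr(sample, "node_features")))
    if not scenario_ok:
        raise TransferError(
            "pretrained model scenario does not match the target graphs")
    model = initialize_from(pretrained)
    trainable = "head" if mode == "linear_only" else "all"
    return train_model(model, ds, graphs, split, cfg, seed=seed,
                       trainable=trainable)
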