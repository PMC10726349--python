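"""Train/validation/test partitioning with IL-level test isolation.

The test set is drawn exclusively from expert-vetted (clean) records at
whole-ionic-liquid granularity: a seeded shuffle of the clean ILs is
consumed until the selected ILs' records first reach the requested record
fraction (10% by default), and *every* record of a selected IL is held
out.  The remaining records are split 5:1 between training and validation
(75:15:10 overall on a uniform clean dataset), either at record level
(``random``) or at whole-IL level (``restricted``, no IL contributes to
both train and validation).  The same test ILs can be reused across clean
and raw variants of a dataset so their scores stay comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import PropertyDataset
from .errors import SplitError

logger = logging.getLogger(__name__)

SPLIT_MODES = ("random", "restricted")


@dataclass(frozen=True)
class SplitAssignment:
    record_partition: dict           # record_id -> 'train' | 'val' | 'test'
    test_il_ids: frozenset
    mode: str
    seed: int

    def records(self, part: str) -> np.ndarray:
        return np.array(sorted(
            rid for rid, p in self.record_partition.items() if p == part),
            dtype=object)

    def counts(self) -> dict:
        parts = list(self.record_partition.values())
        return {p: parts.count(p) for p in ("train", "val", "test")}


def select_test_ils(clean_ds: PropertyDataset, fraction: float = 0.10,
                    seed: int = 0) -> set:
    """Pick whole ILs for the test set until their records reach `fraction`
    of the clean dataset (seeded, deterministic)."""
    if len(clean_ds) == 0:
        raise SplitError("cannot select test ILs from an empty dataset")
    if not 0.0 < fraction < 1.0:
        raise SplitError("test fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    il_ids = np.array(clean_ds.il_ids, dtype=object)
    rng.shuffle(il_ids)
    counts = clean_ds.frame.groupby("il_id").size()
    target = fraction * len(clean_ds)
    chosen, total = [], 0
    for il in il_ids:
        chosen.append(il)
        total += int(counts[il])
        if total >= target:
            break
    if total < target:
        logger.warning(
            "test fraction %.3f unreachable; selected all %d ILs",
            fraction, len(chosen))
    if total > target and len(chosen) == 1:
        logger.warning(
            "single test IL overshoots the %.3f record fraction", fraction)
    return set(chosen)


def assign_splits(ds: PropertyDataset, test_ils: set, mode: str = "random",
                  seed: int = 0, val_ratio: float = 1.0 / 6.0
                  ) -> SplitAssignment:
    """Partition records into train/val/test honoring the test ILs.

    ``val_ratio`` is the validation share of the *non-test* records (1/6
    gives the 5:1 train:validation split, hence 75:15:10 overall when the
    test records are 10%).
    """
    if mode not in SPLIT_MODES:
        raise SplitError(f"unknown split mode '{mode}'")
    frame = ds.frame
    ds_ils = set(frame["il_id"])
    missing = set(test_ils) - ds_ils
    if missing:
        raise SplitError(
            f"test ILs absent from the dataset: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    is_test = frame["il_id"].isin(set(test_ils)).to_numpy()
    partition = {}
    for rid in frame.loc[is_test, "record_id"]:
        partition[rid] = "test"

    rest = frame[~is_test]
    n_rest = len(rest)
    if n_rest == 0:
        raise SplitError("no records left for training and validation")
    n_val = int(round(n_rest * val_ratio))

    if mode == "random":
        order = rng.permutation(n_rest)
        val_rows = set(order[:n_val])
        for pos, rid in enumerate(rest["record_id"]):
            partition[rid] = "val" if pos in val_rows else "train"
    else:  # restricted: whole ILs go to either train or val
        rest_ils = np.array(list(dict.fromkeys(rest["il_id"])), dtype=object)
        rng.shuffle(rest_ils)
        counts = rest.groupby("il_id").size()
        val_ils, total = set(), 0
        for il in rest_ils:
            if total >= n_val:
                break
            val_ils.add(il)
            total += int(counts[il])
        for rid, il in zip(rest["record_id"], rest["il_id"]):
            partition[rid] = "val" if il in val_ils else "train"

    assignment = SplitAssignment(record_partition=partition,
                                 test_il_ids=frozenset(test_ils),
                                 mode=mode, seed=seed)
    _check_leakage(ds, assignment)
    return assignment


def _check_leakage(ds: PropertyDataset, assignment: SplitAssignment):
    frame = ds.frame
    part = frame["record_id"].map(assignment.record_partition)
    test_ils = set(frame.loc[part == "test", "il_id"])
    trainval_ils = set(frame.loc[part != "test", "il_id"])
    leaked = test_ils & trainval_ils
    if leaked:
        raise SplitError(f"test ILs leaked into train/val: "
                         f"{sorted(leaked)[:5]}")
    if assignment.mode == "restricted":
        train_ils = set(frame.loc[part == "train", "il_id"])
        val_ils = set(frame.loc[part == "val", "il_id"])
        shared = train_ils & val_ils
        if shared:
            raise SplitError(
                f"restricted split shares ILs across train/val: "
                f"{sorted(shared)[:5]}")
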