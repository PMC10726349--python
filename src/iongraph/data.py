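"""Tabular property measurements: one row per (ionic liquid, conditions).

CSV schema (shared by the synthetic generator, the curation CLI and the
training pipeline)::

    record_id, il_id, cation_smiles, anion_smiles, temperature_K,
    pressure_kPa, value, quality

``quality`` is ``clean`` (expert-vetted) or ``raw`` (as-collected, may be
mislabeled); ``pressure_kPa`` is optional (empty for properties measured
at ambient pressure).  A ``ground_truth`` column may be carried by
synthetic datasets for oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CurationError

REQUIRED_COLUMNS = ("il_id", "cation_smiles", "anion_smiles",
                    "temperature_K", "value", "quality")
QUALITY_LEVELS = ("clean", "raw")


@dataclass(frozen=True)
class PropertyDataset:
    """Immutable wrapper around a measurement table."""

    frame: pd.DataFrame

    @staticmethod
    def from_frame(frame: pd.DataFrame) -> "PropertyDataset":
        frame = frame.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise CurationError(f"dataset is missing columns: {missing}")
        bad = set(frame["quality"].unique()) - set(QUALITY_LEVELS)
        if bad:
            raise CurationError(f"unknown quality flags: {sorted(bad)}")
        if "record_id" not in frame.columns:
            frame.insert(0, "record_id", np.arange(len(frame)))
        if "pressure_kPa" not in frame.columns:
            frame["pressure_kPa"] = np.nan
        frame = frame.reset_index(drop=True)
        return PropertyDataset(frame)

    @staticmethod
    def from_csv(path) -> "PropertyDataset":
        return PropertyDataset.from_frame(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    # -- views ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy(dtype=float)

    @property
    def record_ids(self) -> np.ndarray:
        return self.frame["record_id"].to_numpy()

    @property
    def il_ids(self) -> list:
        return list(pd.unique(self.frame["il_id"]))

    @property
    def has_pressure(self) -> bool:
        return bool(self.frame["pressure_kPa"].notna().all())

    def clean_subset(self) -> "PropertyDataset":
        return PropertyDataset(
            self.frame[self.frame["quality"] == "clean"]
            .reset_index(drop=True))

    def subset_records(self, record_ids) -> "PropertyDataset":
        mask = self.frame["record_id"].isin(set(record_ids))
        return PropertyDataset(self.frame[mask].reset_index(drop=True))

    def subset_ils(self, il_ids) -> "PropertyDataset":
        mask = self.frame["il_id"].isin(set(il_ids))
        return PropertyDataset(self.frame[mask].reset_index(drop=True))

    def drop_mask(self, mask: np.ndarray) -> "PropertyDataset":
        return PropertyDataset(
            self.frame[~np.asarray(mask, dtype=bool)]
            .reset_index(drop=True))

    def ion_pairs(self) -> pd.DataFrame:
        """One row per unique ionic liquid."""
        return (self.frame[["il_id", "cation_smiles", "anion_smiles"]]
                .drop_duplicates("il_id").reset_index(drop=True))

    def conditions(self, n_conditions: int) -> np.ndarray:
        """(n_records, n_conditions) matrix: temperature, then pressure."""
        if n_conditions == 1:
            return self.frame[["temperature_K"]].to_numpy(dtype=float)
        if n_conditions == 2:
            return self.frame[["temperature_K", "pressure_kPa"]].to_numpy(
                dtype=float)
        raise CurationError(f"unsupported condition count {n_conditions}")
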