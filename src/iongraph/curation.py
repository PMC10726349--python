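"""Robust outlier detection and distribution diagnostics for property data.

Three detectors over the property column, applied globally:

* ``zscore`` — |x − mean| / sd > threshold (default 3; not robust);
* ``iqr``    — x outside [Q1 − k·IQR, Q3 + k·IQR] (default k = 1.5);
* ``mad``    — |x − median| > k·MAD (default k = 3.0), where MAD is the
  unscaled median absolute deviation from the median.

MAD and IQR tolerate heavy-tailed, skewed property distributions (e.g.
viscosity); the z-score breaks down when outliers inflate the standard
deviation.  Skewness is the adjusted Fisher–Pearson sample estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import PropertyDataset
from .errors import CurationError

logger = logging.getLogger(__name__)

DETECTION_METHODS = ("none", "zscore", "iqr", "mad")
DEFAULT_THRESHOLDS = {"zscore": 3.0, "iqr": 1.5, "mad": 3.0}


@dataclass(frozen=True)
class OutlierReport:
    method: str
    threshold: float
    flagged_mask: np.ndarray
    fraction_removed: float
    skewness_before: float
    skewness_after: float

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "threshold": float(self.threshold),
            "n_flagged": int(self.flagged_mask.sum()),
            "fraction_removed": float(self.fraction_removed),
            "skewness_before": float(self.skewness_before),
            "skewness_after": float(self.skewness_after),
        }


def detect_outliers(values: np.ndarray, method: str,
                    threshold: float | None = None) -> np.ndarray:
    """Boolean mask, True where a value is flagged as an outlier."""
    values = np.asarray(values, dtype=float)
    if method not in DETECTION_METHODS:
        raise CurationError(f"unknown detection method '{method}'")
    if method == "none":
        return np.zeros(values.shape, dtype=bool)
    if values.size < 4 or not np.all(np.isfinite(values)):
        raise CurationError(
            "outlier detection needs at least 4 finite values")
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[method]
    if threshold <= 0:
        raise CurationError("threshold must be positive")

    if method == "zscore":
        sd = values.std(ddof=0)
        if sd == 0.0:
            logger.warning("zero standard deviation; no z-score outliers")
            return np.zeros(values.shape, dtype=bool)
        return np.abs(values - values.mean()) / sd > threshold
    if method == "iqr":
        q1, q3 = np.percentile(values, [25, 75])
        iqr = q3 - q1
        return (values < q1 - threshold * iqr) | (
            values > q3 + threshold * iqr)
    # mad
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0.0:
        logger.warning("zero MAD; no MAD outliers")
        return np.zeros(values.shape, dtype=bool)
    return np.abs(values - med) > threshold * mad


def skewness(values: np.ndarray) -> float:
    """Adjusted Fisher–Pearson sample skewness."""
    values = np.asarray(values, dtype=float)
    if values.size < 3 or not np.all(np.isfinite(values)):
        raise CurationError("skewness needs at least 3 finite values")
    if values.std(ddof=0) == 0.0:
        raise CurationError("skewness undefined for zero-variance data")
    return float(stats.skew(values, bias=False))


def curate_dataset(ds: PropertyDataset, method: str,
                   threshold: float | None = None,
                   per_il: bool = False):
    """Remove flagged records; return (filtered dataset, OutlierReport).

    Detection runs globally over the property column by default; set
    ``per_il`` to stratify the detectors within each ionic liquid.
    """
    if len(ds) == 0:
        raise CurationError("cannot curate an empty dataset")
    values = ds.values
    if method == "none":
        mask = np.zeros(len(ds), dtype=bool)
    elif per_il:
        mask = np.zeros(len(ds), dtype=bool)
        for _, idx in ds.frame.groupby("il_id").groups.items():
            idx = np.asarray(idx)
            if idx.size >= 4:
                mask[idx] = detect_outliers(values[idx], method, threshold)
    else:
        mask = detect_outliers(values, method, threshold)
    if mask.all():
        raise CurationError("all records flagged as outliers")
    kept = ds.drop_mask(mask)
    skew_before = (skewness(values)
                   if values.size >= 3 and values.std() > 0
                   else float("nan"))
    kept_values = kept.values
    skew_after = (skewness(kept_values)
                  if kept_values.size >= 3 and kept_values.std() > 0
                  else float("nan"))
    report = OutlierReport(
        method=method,
        threshold=float(DEFAULT_THRESHOLDS.get(method, 0.0)
                        if threshold is None else threshold),
        flagged_mask=mask,
        fraction_removed=float(mask.mean()),
        skewness_before=skew_before,
        skewness_after=skew_after,
    )
    return kept, report
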