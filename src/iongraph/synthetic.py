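"""Synthetic ionic-liquid libraries and property datasets with known truth.

The generator emulates the *shape* of curated IL property databases —
repeated measurements per IL over a temperature (and optionally pressure)
grid, a property varying smoothly with conditions plus structure-dependent
terms, and a configurable fraction of grossly mislabeled "raw" rows — not
their physics.  Cations are templated imidazolium / pyridinium /
tetraalkylammonium / tetraalkylphosphonium scaffolds with seeded alkyl
chain lengths (1–12 carbons); anions come from a fixed library of common
IL anions.  The ground truth is linear in graph-computable descriptors
(heavy-atom counts per ion, aromatic-atom count, aliphatic-carbon count)
so a graph network can in principle recover it exactly; the default
coefficients give a surface-tension-like scale (tens of mN/m, decreasing
with temperature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .data import PropertyDataset
from .errors import IonGraphError
from .ions import IonPair, parse_ion_pair

T_REF = 298.15       # K
P_REF = 100.0        # kPa

CATION_SCAFFOLDS = (
    ("imidazolium", "{chain}[n+]1ccn(C)c1"),
    ("pyridinium", "{chain}[n+]1ccccc1"),
    ("ammonium", "C[N+](C)(C){chain}"),
    ("phosphonium", "C[P+](C)(C){chain}"),
)
MAX_CHAIN = 12

ANION_LIBRARY = (
    ("chloride", "[Cl-]"),
    ("bromide", "[Br-]"),
    ("iodide", "[I-]"),
    ("tetrafluoroborate", "[B-](F)(F)(F)F"),
    ("dicyanamide", "N#C[N-]C#N"),
    ("methylsulfate", "COS(=O)(=O)[O-]"),
    ("ethylsulfate", "CCOS(=O)(=O)[O-]"),
    ("butylsulfate", "CCCCOS(=O)(=O)[O-]"),
    ("hydrogensulfate", "OS(=O)(=O)[O-]"),
    ("mesylate", "CS(=O)(=O)[O-]"),
    ("triflate", "C(F)(F)(F)S(=O)(=O)[O-]"),
    ("acetate", "CC(=O)[O-]"),
)

DESCRIPTOR_NAMES = ("cation_heavy", "anion_heavy", "aromatic_atoms",
                    "aliphatic_carbons")

DEFAULT_COEFFICIENTS = {
    "intercept": 55.0,
    "cation_heavy": -0.6,
    "anion_heavy": 0.8,
    "aromatic_atoms": 0.5,
    "aliphatic_carbons": -0.35,
    "temperature": -0.08,    # per K, relative to T_REF
    "pressure": 0.002,       # per kPa, relative to P_REF
}

DEFAULT_TEMPS = tuple(283.15 + 10.0 * k for k in range(8))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_cations: int = 30
    n_anions: int = 10
    temps: tuple = DEFAULT_TEMPS
    pressures: tuple | None = None
    coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    noise_sd: float = 0.1
    mislabel_fraction: float = 0.0
    mislabel_scale: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cations * self.n_anions < 2:
            raise IonGraphError("ion library must contain >= 2 pairs")
        if not 0.0 <= self.mislabel_fraction < 1.0:
            raise IonGraphError("mislabel fraction must lie in [0, 1)")
        if self.mislabel_scale <= 1.0:
            raise IonGraphError("mislabel scale must exceed 1")


def generate_ion_library(n_cations: int, n_anions: int,
                         seed: int = 0) -> list:
    """All cation×anion pairs from seeded scaffold/chain-length draws."""
    if n_cations < 1 or n_anions < 1:
        raise IonGraphError("ion counts must be >= 1")
    n_cation_pool = len(CATION_SCAFFOLDS) * MAX_CHAIN
    if n_cations > n_cation_pool:
        raise IonGraphError(f"at most {n_cation_pool} distinct cations "
                            "are available")
    if n_anions > len(ANION_LIBRARY):
        raise IonGraphError(f"at most {len(ANION_LIBRARY)} distinct anions "
                            "are available")
    rng = np.random.default_rng(seed)
    pool = [(name, template.format(chain="C" * k))
            for name, template in CATION_SCAFFOLDS
            for k in range(1, MAX_CHAIN + 1)]
    cation_rows = [pool[i] for i in
                   rng.choice(n_cation_pool, size=n_cations, replace=False)]
    anion_rows = [ANION_LIBRARY[i] for i in
                  rng.choice(len(ANION_LIBRARY), size=n_anions,
                             replace=False)]
    pairs = []
    for ci, (cname, csmi) in enumerate(cation_rows):
        for ai, (aname, asmi) in enumerate(anion_rows):
            pairs.append(parse_ion_pair(
                csmi, asmi, il_id=f"il-{ci:03d}-{ai:03d}"))
    return pairs


def compute_descriptors(pair: IonPair) -> dict:
    """Graph-computable structural descriptors of an ion pair."""
    cat = Chem.MolFromSmiles(pair.cation_smiles)
    an = Chem.MolFromSmiles(pair.anion_smiles)
    if cat is None or an is None:
        raise IonGraphError(f"descriptor failure for {pair.il_id}")
    aromatic = sum(a.GetIsAromatic() for m in (cat, an)
                   for a in m.GetAtoms())
    aliphatic_c = sum(a.GetAtomicNum() == 6 and not a.GetIsAromatic()
                      for m in (cat, an) for a in m.GetAtoms())
    return {
        "cation_heavy": cat.GetNumAtoms(),
        "anion_heavy": an.GetNumAtoms(),
        "aromatic_atoms": aromatic,
        "aliphatic_carbons": aliphatic_c,
    }


def ground_truth_value(descriptors: dict, coefficients: dict,
                       temperature: float, pressure: float | None) -> float:
    y = coefficients["intercept"]
    for name in DESCRIPTOR_NAMES:
        y += coefficients[name] * descriptors[name]
    y += coefficients["temperature"] * (temperature - T_REF)
    if pressure is not None:
        y += coefficients.get("pressure", 0.0) * (pressure - P_REF)
    return float(y)


def synthesize_dataset(pairs, spec: SyntheticSpec) -> PropertyDataset:
    """Measurement grid over (pairs × temps × pressures) with known truth.

    All rows are flagged clean; use :func:`inject_mislabels` to corrupt a
    subset into raw-only rows.
    """
    rng = np.random.default_rng(spec.seed)
    pressures = spec.pressures if spec.pressures else (None,)
    rows = []
    for pair in pairs:
        desc = compute_descriptors(pair)
        for temp in spec.temps:
            for pressure in pressures:
                truth = ground_truth_value(desc, spec.coefficients,
                                           temp, pressure)
                rows.append({
                    "il_id": pair.il_id,
                    "cation_smiles": pair.cation_smiles,
                    "anion_smiles": pair.anion_smiles,
                    "temperature_K": temp,
                    "pressure_kPa": (np.nan if pressure is None
                                     else pressure),
                    "ground_truth": truth,
                    "quality": "clean",
                })
    frame = pd.DataFrame(rows)
    noise = (rng.normal(0.0, spec.noise_sd, size=len(frame))
             if spec.noise_sd > 0 else np.zeros(len(frame)))
    frame["value"] = frame["ground_truth"] + noise
    ds = PropertyDataset.from_frame(frame)
    if spec.mislabel_fraction > 0:
        ds, _ = inject_mislabels(ds, spec.mislabel_fraction,
                                 spec.mislabel_scale, spec.seed + 1)
    return ds


def inject_mislabels(ds: PropertyDataset, fraction: float, scale: float,
                     seed: int = 0):
    """Corrupt a seeded random subset of records by ×scale or ÷scale.

    Exactly ``round(fraction·n)`` records are multiplied or divided by
    ``scale`` (fair coin per record) and re-flagged ``raw``; all other
    records are untouched.  Returns ``(dataset, corrupted_record_ids)``.
    """
    if not 0.0 <= fraction < 1.0:
        raise IonGraphError("mislabel fraction must lie in [0, 1)")
    if scale <= 1.0:
        raise IonGraphError("mislabel scale must exceed 1")
    n = len(ds)
    n_corrupt = int(round(fraction * n))
    if n_corrupt == 0:
        return ds, np.array([], dtype=ds.record_ids.dtype)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_corrupt, replace=False)
    frame = ds.frame.copy()
    factors = np.where(rng.random(n_corrupt) < 0.5, scale, 1.0 / scale)
    frame.loc[frame.index[idx], "value"] *= factors
    frame.loc[frame.index[idx], "quality"] = "raw"
    corrupted = frame.loc[frame.index[idx], "record_id"].to_numpy()
    return PropertyDataset.from_frame(frame), corrupted
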