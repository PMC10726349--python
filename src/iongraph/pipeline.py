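"""End-to-end featurization: SMILES pairs → model-ready graphs.

Geometries and charges are cached per unique ion SMILES (scenario A/C)
or per ionic liquid (scenario B, where the pair is relaxed jointly and
counterion screening changes the charges), so large measurement tables
featurize in time proportional to the number of distinct ions.
"""

from __future__ import annotations

import logging

from .data import PropertyDataset
from .errors import GeometryError, ScenarioError
from .graphs import (add_virtual_ionic_bond, build_graph_pair,
                     build_ion_graph, build_joint_graph,
                     merge_block_diagonal)
from .ions import (IonPair, assign_partial_charges, generate_geometry,
                   parse_ion_pair)

logger = logging.getLogger(__name__)


class GraphFeaturizer:
    """Configured ion-pair → graph conversion with per-ion caching."""

    def __init__(self, scenario: str = "a", engine: str = "rdkit",
                 charge_scheme: str = "formal", ionic_bond: bool = True,
                 pooling_mode: str = "separate", embed_seed: int = 17,
                 n_conformers: int = 10):
        if scenario not in ("a", "b", "c"):
            raise ScenarioError(f"unknown scenario '{scenario}'")
        if scenario == "c" and ionic_bond:
            raise ScenarioError(
                "Virtual ionic bonds are applicable only in scenarios "
                "A and B")
        self.scenario = scenario
        self.engine = engine
        self.charge_scheme = charge_scheme
        self.ionic_bond = ionic_bond
        self.pooling_mode = pooling_mode
        self.embed_seed = embed_seed
        self.n_conformers = n_conformers
        self._ion_graphs = {}       # ion smiles -> single-ion graph

    # -- single-ion graphs (scenarios a and c) -------------------------
    def _ion_graph(self, pair: IonPair, which: str):
        smiles = (pair.cation_smiles if which == "cation"
                  else pair.anion_smiles)
        if smiles not in self._ion_graphs:
            geom_cat, geom_an = generate_geometry(
                pair, mode="separate", engine=self.engine,
                embed_seed=self.embed_seed,
                n_conformers=self.n_conformers)
            for smi, geom in ((pair.cation_smiles, geom_cat),
                              (pair.anion_smiles, geom_an)):
                if smi not in self._ion_graphs:
                    charges = assign_partial_charges(
                        geom, self.charge_scheme)
                    self._ion_graphs[smi] = build_ion_graph(geom, charges)
        return self._ion_graphs[smiles]

    def __call__(self, pair: IonPair):
        """Graph (scenario a/b) or GraphPair (scenario c) for one IL."""
        if self.scenario == "b":
            geom = generate_geometry(
                pair, mode="joint", engine=self.engine,
                embed_seed=self.embed_seed,
                n_conformers=self.n_conformers)
            charges = assign_partial_charges(geom, self.charge_scheme)
            graph = build_joint_graph(geom, charges)
            return (add_virtual_ionic_bond(graph) if self.ionic_bond
                    else graph)
        g_cat = self._ion_graph(pair, "cation")
        g_an = self._ion_graph(pair, "anion")
        if self.scenario == "a":
            graph = merge_block_diagonal(g_cat, g_an)
            return (add_virtual_ionic_bond(graph) if self.ionic_bond
                    else graph)
        return build_graph_pair(g_cat, g_an, self.pooling_mode)


def featurize_pairs(pairs, featurizer: GraphFeaturizer,
                    skip_failures: bool = False) -> dict:
    """il_id → graph mapping; optionally skip-and-log geometry failures."""
    graphs = {}
    for pair in pairs:
        try:
            graphs[pair.il_id] = featurizer(pair)
        except GeometryError:
            if not skip_failures:
                raise
            logger.warning("skipping %s: geometry failure", pair.il_id)
    return graphs


def dataset_pairs(ds: PropertyDataset) -> list:
    """Validated IonPair objects, one per unique IL in the dataset."""
    return [parse_ion_pair(row.cation_smiles, row.anion_smiles, row.il_id)
            for row in ds.ion_pairs().itertuples()]


def featurize_dataset(ds: PropertyDataset, featurizer: GraphFeaturizer,
                      skip_failures: bool = False) -> dict:
    return featurize_pairs(dataset_pairs(ds), featurizer, skip_failures)
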