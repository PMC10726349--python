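"""Ion-pair parsing, 3D geometry generation, and partial-charge assignment.

An ionic liquid is modelled as a (cation, anion) SMILES pair with net
charge zero.  Geometries are produced by a seeded conformational search
(multiple ETKDG embeddings, lowest force-field energy kept) and refined
either with RDKit's MMFF94/UFF implementation or with Open Babel's
``mmff94``/``uff`` local optimizer.  Molecular graphs downstream use a
heavy-atom representation: hydrogens are folded into a per-atom count and
their partial charges are summed onto the bonded heavy atom, so every
charge scheme conserves the ion's net charge over the graph nodes.

Charge schemes: ``none`` (zeros), ``formal`` (valence bookkeeping),
``gasteiger`` (electronegativity equalization), ``mmff94`` (force-field
parametrization), ``qtpie`` (charge transfer with polarization; Open Babel
only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

from .errors import (CapabilityError, ChargeBalanceError,
                     ChargeComputationError, GeometryError, ParseError)

RDLogger.DisableLog("rdApp.*")

ENGINES = ("rdkit", "openbabel")
CHARGE_SCHEMES = ("none", "formal", "gasteiger", "mmff94", "qtpie")

# centroid separation (Angstrom) used to seed joint cation+anion relaxation
JOINT_PLACEMENT_DISTANCE = 4.0

_HYB_MAP = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


def _pybel():
    try:
        from openbabel import openbabel as ob
        from openbabel import pybel
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise CapabilityError(
            "the 'openbabel' backend requires the openbabel python "
            "bindings") from exc
    ob.obErrorLog.SetOutputLevel(0)
    return pybel, ob


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonPair:
    """A cation/anion SMILES pair; the unit of chemical identity."""

    il_id: str
    cation_smiles: str
    anion_smiles: str


@dataclass
class IonGeometry:
    """Heavy-atom 3D structure of one ion (or a jointly relaxed pair)."""

    elements: list
    coordinates: np.ndarray            # (n, 3) Angstrom
    bonds: list                        # (i, j, order in {1,2,3}, aromatic)
    formal_charges: np.ndarray
    h_counts: np.ndarray
    hybridizations: list
    engine: str
    cation_atom_count: int | None = None   # set for joint-mode geometries
    _rdmol: object = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def net_charge(self) -> int:
        return int(self.formal_charges.sum())

    def validate(self):
        n = self.n_atoms
        if not np.all(np.isfinite(self.coordinates)):
            raise GeometryError("non-finite coordinates")
        if self.coordinates.shape != (n, 3):
            raise GeometryError("coordinate matrix shape mismatch")
        for i, j, order, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise GeometryError(f"bond index ({i},{j}) out of range")
            if order not in (1, 2, 3):
                raise GeometryError(f"unexpected bond order {order}")
        if self.cation_atom_count is not None and not (
                0 < self.cation_atom_count < n):
            raise GeometryError("cation atom count out of range")
        return self


@dataclass(frozen=True)
class ChargeVector:
    """Per-heavy-atom charges (elementary charge units) under one scheme."""

    scheme: str
    values: np.ndarray

    def __post_init__(self):
        if self.scheme not in CHARGE_SCHEMES:
            raise CapabilityError(f"unknown charge scheme '{self.scheme}'")
        if not np.all(np.isfinite(self.values)):
            raise ChargeComputationError(
                f"non-finite charges under scheme '{self.scheme}'")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_ion_pair(cation_smiles: str, anion_smiles: str, il_id: str,
                   charge_magnitude: int = 1) -> IonPair:
    """Parse and validate a cation/anion pair.

    Charges must be +`charge_magnitude` for the cation and the negation for
    the anion (monovalent by default); SMILES are canonicalized so equal
    ions deduplicate.
    """
    if not cation_smiles or not anion_smiles:
        raise ParseError("empty SMILES string")
    mols = {}
    for role, smi in (("cation", cation_smiles), ("anion", anion_smiles)):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ParseError(f"unparseable {role} SMILES: '{smi}'")
        mols[role] = mol
    q_cat = Chem.GetFormalCharge(mols["cation"])
    q_an = Chem.GetFormalCharge(mols["anion"])
    if q_cat != charge_magnitude:
        raise ChargeBalanceError(
            f"cation '{cation_smiles}' has charge {q_cat:+d}, "
            f"expected {charge_magnitude:+d}")
    if q_an != -charge_magnitude:
        raise ChargeBalanceError(
            f"anion '{anion_smiles}' has charge {q_an:+d}, "
            f"expected {-charge_magnitude:+d}")
    return IonPair(il_id=il_id,
                   cation_smiles=Chem.MolToSmiles(mols["cation"]),
                   anion_smiles=Chem.MolToSmiles(mols["anion"]))


# ---------------------------------------------------------------------------
# geometry generation
# ---------------------------------------------------------------------------

def _embed_conformers(smiles: str, seed: int, n_conformers: int) -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_conformers,
                                     params=params)
    if len(ids) == 0:
        params.useRandomCoords = True
        ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_conformers,
                                         params=params)
    if len(ids) == 0:
        raise GeometryError(f"3D embedding failed for '{smiles}'")
    return mol


def _rdkit_optimize(mol: Chem.Mol) -> int:
    """Force-field optimize all conformers in place; return best conf id."""
    if mol.GetNumAtoms() == 1:
        return 0
    if AllChem.MMFFHasAllMoleculeParams(mol):
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
    else:
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=500)
    energies = [e for _, e in results]
    return int(np.argmin(energies))


def _openbabel_optimize(mol: Chem.Mol) -> int:
    """Refine each conformer with Open Babel local optimization."""
    pybel, ob = _pybel()
    best_id, best_energy = None, np.inf
    coords_by_id = {}
    for conf in mol.GetConformers():
        block = Chem.MolToMolBlock(mol, confId=conf.GetId())
        pmol = pybel.readstring("mol", block)
        ff_name = "mmff94"
        ff = ob.OBForceField.FindForceField(ff_name)
        if ff is None or not ff.Setup(pmol.OBMol):
            ff_name = "uff"
            ff = ob.OBForceField.FindForceField(ff_name)
            if ff is None or not ff.Setup(pmol.OBMol):
                raise GeometryError(
                    "Open Babel force-field setup failed for an ion")
        if len(pmol.atoms) > 1:
            pmol.localopt(forcefield=ff_name, steps=500)
            ff.Setup(pmol.OBMol)
        energy = ff.Energy()
        coords_by_id[conf.GetId()] = np.array(
            [a.coords for a in pmol.atoms])
        if energy < best_energy:
            best_energy, best_id = energy, conf.GetId()
    for conf in mol.GetConformers():
        coords = coords_by_id[conf.GetId()]
        for i in range(mol.GetNumAtoms()):
            conf.SetAtomPosition(i, coords[i].tolist())
    return int(best_id)


def _keep_single_conformer(mol: Chem.Mol, conf_id: int) -> Chem.Mol:
    out = Chem.Mol(mol)
    out.RemoveAllConformers()
    conf = Chem.Conformer(mol.GetConformer(conf_id))
    conf.SetId(0)
    out.AddConformer(conf, assignId=False)
    return out


def _geometry_from_mol(mol_h: Chem.Mol, engine: str,
                       cation_atom_count: int | None = None) -> IonGeometry:
    """Extract the heavy-atom geometry record from a hydrogen-explicit mol."""
    kek = Chem.Mol(mol_h)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    heavy = [a.GetIdx() for a in mol_h.GetAtoms() if a.GetAtomicNum() != 1]
    index_of = {old: new for new, old in enumerate(heavy)}
    conf = mol_h.GetConformer()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in heavy])
    atoms = [mol_h.GetAtomWithIdx(i) for i in heavy]
    bonds = []
    for bond in mol_h.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in index_of and j in index_of:
            order = int(kek.GetBondBetweenAtoms(i, j).GetBondTypeAsDouble())
            bonds.append((index_of[i], index_of[j], order,
                          bond.GetIsAromatic()))
    geom = IonGeometry(
        elements=[a.GetAtomicNum() for a in atoms],
        coordinates=coords,
        bonds=bonds,
        formal_charges=np.array([a.GetFormalCharge() for a in atoms],
                                dtype=int),
        h_counts=np.array([a.GetTotalNumHs() for a in atoms], dtype=int),
        # monoatomic ions carry no meaningful hybridization
        hybridizations=[("other" if a.GetDegree() == 0
                         else _HYB_MAP.get(a.GetHybridization(), "other"))
                        for a in atoms],
        engine=engine,
        cation_atom_count=cation_atom_count,
        _rdmol=mol_h,
    )
    return geom.validate()


def _embed_and_optimize(smiles: str, engine: str, seed: int,
                        n_conformers: int) -> Chem.Mol:
    mol = _embed_conformers(smiles, seed, n_conformers)
    try:
        best = (_rdkit_optimize(mol) if engine == "rdkit"
                else _openbabel_optimize(mol))
    except GeometryError:
        raise
    except Exception as exc:
        raise GeometryError(
            f"force-field optimization failed for '{smiles}': {exc}") from exc
    return _keep_single_conformer(mol, best)


def generate_geometry(pair: IonPair, mode: str = "separate",
                      engine: str = "rdkit", embed_seed: int = 17,
                      n_conformers: int = 10):
    """Build optimized 3D geometries for an ion pair.

    mode="separate" returns ``(cation_geometry, anion_geometry)``;
    mode="joint" places the separately embedded ions 4 A apart (centroid
    distance), relaxes the complex as one system, and returns a single
    geometry whose cation atoms precede the anion atoms
    (``cation_atom_count`` records the boundary).  Deterministic for fixed
    (pair, mode, engine, embed_seed, n_conformers).
    """
    if engine not in ENGINES:
        raise CapabilityError(f"unknown engine '{engine}'")
    if mode not in ("separate", "joint"):
        raise CapabilityError(f"unknown geometry mode '{mode}'")
    try:
        cat = _embed_and_optimize(pair.cation_smiles, engine, embed_seed,
                                  n_conformers)
        an = _embed_and_optimize(pair.anion_smiles, engine, embed_seed + 1,
                                 n_conformers)
    except GeometryError as exc:
        raise GeometryError(f"[{pair.il_id}] {exc}") from exc
    if mode == "separate":
        return (_geometry_from_mol(cat, engine),
                _geometry_from_mol(an, engine))

    # joint mode: translate the anion along +x to the placement distance,
    # then relax the complex with the chosen engine.
    cat_centroid = _centroid(cat)
    an_centroid = _centroid(an)
    shift = (cat_centroid + np.array([JOINT_PLACEMENT_DISTANCE, 0.0, 0.0])
             - an_centroid)
    an_conf = an.GetConformer()
    for i in range(an.GetNumAtoms()):
        pos = np.array(list(an_conf.GetAtomPosition(i))) + shift
        an_conf.SetAtomPosition(i, pos.tolist())
    combo = Chem.CombineMols(cat, an)
    Chem.SanitizeMol(combo)
    try:
        if engine == "rdkit":
            if AllChem.MMFFHasAllMoleculeParams(combo):
                AllChem.MMFFOptimizeMolecule(combo, maxIters=500)
            else:
                AllChem.UFFOptimizeMolecule(combo, maxIters=500)
        else:
            best = _openbabel_optimize(combo)
            combo = _keep_single_conformer(combo, best)
    except Exception as exc:
        raise GeometryError(
            f"[{pair.il_id}] joint relaxation failed: {exc}") from exc
    n_cat_heavy = sum(1 for a in cat.GetAtoms() if a.GetAtomicNum() != 1)
    return _geometry_from_mol(combo, engine,
                              cation_atom_count=n_cat_heavy)


def _centroid(mol: Chem.Mol) -> np.ndarray:
    conf = mol.GetConformer()
    return np.array([list(conf.GetAtomPosition(i))
                     for i in range(mol.GetNumAtoms())]).mean(axis=0)


# ---------------------------------------------------------------------------
# partial charges
# ---------------------------------------------------------------------------

def _fold_hydrogens(mol_h: Chem.Mol, charges_full: np.ndarray) -> np.ndarray:
    """Sum hydrogen charges onto their bonded heavy atom."""
    heavy = [a.GetIdx() for a in mol_h.GetAtoms() if a.GetAtomicNum() != 1]
    index_of = {old: new for new, old in enumerate(heavy)}
    out = np.zeros(len(heavy))
    for atom in mol_h.GetAtoms():
        q = charges_full[atom.GetIdx()]
        if atom.GetAtomicNum() != 1:
            out[index_of[atom.GetIdx()]] += q
        else:
            neighbors = atom.GetNeighbors()
            if neighbors:
                out[index_of[neighbors[0].GetIdx()]] += q
    return out


def _openbabel_charges(mol_h: Chem.Mol, model_name: str) -> np.ndarray:
    pybel, ob = _pybel()
    model = ob.OBChargeModel.FindType(model_name)
    if model is None:
        raise CapabilityError(
            f"Open Babel charge model '{model_name}' unavailable")
    pmol = pybel.readstring("mol", Chem.MolToMolBlock(mol_h))
    if not model.ComputeCharges(pmol.OBMol):
        raise ChargeComputationError(
            f"Open Babel '{model_name}' charge computation failed")
    return np.array(list(model.GetPartialCharges()))


def assign_partial_charges(geom: IonGeometry, scheme: str) -> ChargeVector:
    """Assign per-heavy-atom charges under the requested scheme.

    Hydrogen charges are folded into the bonded heavy atom so that the
    vector sums to the ion's net charge.  ``gasteiger`` and ``mmff94`` are
    computed by the geometry's own engine; ``qtpie`` always uses Open Babel.
    """
    n = geom.n_atoms
    if scheme == "none":
        return ChargeVector("none", np.zeros(n))
    if scheme == "formal":
        return ChargeVector("formal", geom.formal_charges.astype(float))
    if scheme not in CHARGE_SCHEMES:
        raise CapabilityError(f"unknown charge scheme '{scheme}'")
    mol_h = geom._rdmol
    if mol_h is None:
        raise CapabilityError(
            f"scheme '{scheme}' needs the full-atom geometry object")
    if scheme == "gasteiger":
        # always via RDKit: its Gasteiger-Marsili honors formal charges,
        # so ion totals are conserved (Open Babel's variant zeroes them)
        AllChem.ComputeGasteigerCharges(mol_h)
        full = np.array([a.GetDoubleProp("_GasteigerCharge")
                         for a in mol_h.GetAtoms()])
    elif scheme == "qtpie" or geom.engine == "openbabel":
        model = {"mmff94": "mmff94", "qtpie": "qtpie"}[scheme]
        full = _openbabel_charges(mol_h, model)
    else:  # mmff94 via RDKit
        props = AllChem.MMFFGetMoleculeProperties(mol_h)
        if props is None:
            raise CapabilityError(
                "MMFF94 parametrization unavailable for this ion")
        full = np.array([props.GetMMFFPartialCharge(i)
                         for i in range(mol_h.GetNumAtoms())])
    values = _fold_hydrogens(mol_h, full)
    vec = ChargeVector(scheme, values)
    total = float(values.sum())
    if abs(total - geom.net_charge) > 0.05:
        warnings.warn(
            f"scheme '{scheme}' total charge {total:.3f} deviates from the "
            f"net ion charge {geom.net_charge:+d}", stacklevel=2)
    return vec


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_sdf(geometries, path: str):
    """Write optimized geometries to an SDF (V2000) file."""
    writer = Chem.SDWriter(str(path))
    try:
        for geom in geometries:
            if geom._rdmol is None:
                raise GeometryError("geometry lacks a full-atom structure")
            writer.write(geom._rdmol)
    finally:
        writer.close()
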