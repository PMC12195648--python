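"""Aligned molecule sets, activity tables and potency arithmetic.

The modeling pipeline operates on *pre-superimposed* 3D conformers: every
molecule in a set shares one coordinate frame, so grid descriptors computed
at the same lattice point are directly comparable across compounds.
Molecules are exchanged as V2000 SDF; per-atom partial charges travel in a
``PARTIAL_CHARGES`` data field (one float per atom, whitespace separated),
since the V2000 atom block has no slot for fractional charges.

Activity is handled in the units potency tables are printed in: IC50 and
GI50 in micromolar, pIC50 = -log10 of the *molar* IC50.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

CHARGE_TAG = "PARTIAL_CHARGES"

#: CoMSIA-style atom property weights by element: (hydrophobicity, HBD, HBA).
#: A deliberately small lookup in the spirit of Viswanadhan-type atomic
#: hydrophobicity classes: carbon and halogens hydrophobic, N/O hydrophilic
#: and H-bond capable.  Editable; pass your own table to ``read_aligned_sdf``.
DEFAULT_PROPERTY_TABLE: dict[str, tuple[float, float, float]] = {
    "H": (0.0, 0.0, 0.0),
    "C": (1.0, 0.0, 0.0),
    "N": (-1.0, 1.0, 1.0),
    "O": (-1.0, 1.0, 1.0),
    "S": (0.5, 0.0, 0.0),
    "P": (0.0, 0.0, 0.0),
    "F": (0.5, 0.0, 1.0),
    "Cl": (1.0, 0.0, 0.0),
    "Br": (1.0, 0.0, 0.0),
    "I": (1.0, 0.0, 0.0),
}

_PT = Chem.GetPeriodicTable()


@dataclass
class Atom:
    """A point atom with the properties the field engine consumes."""

    element: str
    position: np.ndarray  # (3,) Angstrom
    partial_charge: float = 0.0
    vdw_radius: float = 1.7
    hydrophobicity_weight: float = 0.0
    hbd_weight: float = 0.0
    hba_weight: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if not self.vdw_radius > 0:
            raise ValueError("vdw_radius must be positive")
        for w in (self.partial_charge, self.hydrophobicity_weight,
                  self.hbd_weight, self.hba_weight):
            if not math.isfinite(w):
                raise ValueError("atom property weights must be finite")


@dataclass
class AlignedMolecule:
    """One conformer of one compound, in the shared frame of its set."""

    id: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError(f"molecule {self.id!r} has no atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def property_weights(self, label: str) -> np.ndarray:
        """Per-atom weight vector for a CoMSIA field label (S/E/H/D/A)."""
        if label == "S":
            return self.vdw_radii ** 3
        if label == "E":
            return self.charges
        attr = {"H": "hydrophobicity_weight", "D": "hbd_weight",
                "A": "hba_weight"}.get(label)
        if attr is None:
            raise ValueError(f"unknown field label {label!r}")
        return np.array([getattr(a, attr) for a in self.atoms], dtype=float)


@dataclass
class ActivityRecord:
    compound_id: str
    ic50: float | None = None  # micromolar
    pic50: float | None = None
    subset: str = "train"

    def __post_init__(self) -> None:
        if self.ic50 is None and self.pic50 is None:
            raise ValueError(f"{self.compound_id}: need ic50 or pic50")
        if self.ic50 is not None:
            if not self.ic50 > 0:
                raise ValueError(f"{self.compound_id}: ic50 must be > 0")
            if self.pic50 is not None:
                implied = pic50_from_ic50(self.ic50)
                if abs(implied - round(self.pic50, 3)) > 5e-4 + 1e-9:
                    # inconsistent printed pairs do occur in potency tables;
                    # surface the discrepancy, keep both values as given
                    warnings.warn(
                        f"{self.compound_id}: IC50 {self.ic50} uM implies "
                        f"pIC50 {implied}, table says {self.pic50}")
        if self.subset not in ("train", "test"):
            raise ValueError(f"{self.compound_id}: subset must be train/test")

    @property
    def activity(self) -> float:
        return self.pic50 if self.pic50 is not None else pic50_from_ic50(self.ic50)


@dataclass
class CytotoxRecord:
    compound_id: str
    cell_line: str
    gi50: float  # micromolar; a lower bound when censored
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.gi50 > 0:
            raise ValueError("gi50 must be > 0")


def pic50_from_ic50(ic50_um: float) -> float:
    """pIC50 = -log10(IC50 in molar) from a micromolar IC50, to 3 decimals."""
    if not ic50_um > 0:
        raise ValueError("ic50 must be > 0")
    return round(-math.log10(ic50_um * 1e-6), 3)


def ic50_from_pic50(pic50: float) -> float:
    """Inverse of :func:`pic50_from_ic50`, returning micromolar."""
    return 10.0 ** (-pic50) * 1e6


@dataclass
class SelectivityIndex:
    """GI50(non-tumour) / GI50(tumour) with display rounding.

    Potency-ratio tables print SI as an integer once it reaches double
    digits; below that, one decimal is kept.  A censored non-tumour GI50
    (">25") makes the SI itself a lower bound, flagged here.
    """

    value: float
    lower_bound: bool = False

    @property
    def display(self) -> str:
        shown = round(self.value) if self.value >= 10 else round(self.value, 1)
        return f"≥{shown}" if self.lower_bound else f"{shown}"

    @property
    def rounded(self) -> float:
        return float(round(self.value) if self.value >= 10 else round(self.value, 1))


def selectivity_index(gi50_nontumor: float, gi50_tumor: float,
                      nontumor_censored: bool = False) -> SelectivityIndex:
    """Selectivity index between a non-tumour and a tumour cell line."""
    if not (gi50_nontumor > 0 and gi50_tumor > 0):
        raise ValueError("GI50 values must be > 0")
    return SelectivityIndex(gi50_nontumor / gi50_tumor, nontumor_censored)


def _mol_to_aligned(mol: Chem.Mol, idx: int, charge_policy: str,
                    property_table: dict) -> AlignedMolecule:
    if mol.GetNumConformers() == 0:
        raise ValueError(f"record {idx}: no coordinates")
    conf = mol.GetConformer()
    if not conf.Is3D():
        raise ValueError(f"record {idx}: 2D coordinates (flat record)")
    n = mol.GetNumAtoms()

    if charge_policy == "from-file":
        if not mol.HasProp(CHARGE_TAG):
            raise ValueError(
                f"record {idx}: missing {CHARGE_TAG} block "
                "(required with charge_policy='from-file')")
        charges = [float(t) for t in mol.GetProp(CHARGE_TAG).split()]
        if len(charges) != n:
            raise ValueError(f"record {idx}: {len(charges)} charges for {n} atoms")
    elif charge_policy == "compute":
        AllChem.ComputeGasteigerCharges(mol)
        charges = [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()]
        charges = [0.0 if not math.isfinite(c) else c for c in charges]
    else:
        raise ValueError(f"unknown charge_policy {charge_policy!r}")

    name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    atoms = []
    for i, a in enumerate(mol.GetAtoms()):
        sym = a.GetSymbol()
        pos = conf.GetAtomPosition(i)
        hyd, hbd, hba = property_table.get(sym, (0.0, 0.0, 0.0))
        atoms.append(Atom(
            element=sym,
            position=np.array([pos.x, pos.y, pos.z]),
            partial_charge=charges[i],
            vdw_radius=_PT.GetRvdw(a.GetAtomicNum()),
            hydrophobicity_weight=hyd, hbd_weight=hbd, hba_weight=hba,
        ))
    return AlignedMolecule(id=name.strip() or f"mol_{idx}", atoms=atoms)


def read_aligned_sdf(path, charge_policy: str = "from-file",
                     property_table: dict | None = None) -> list[AlignedMolecule]:
    """Read a pre-aligned set from a V2000 SDF.

    ``charge_policy`` is ``"from-file"`` (a ``PARTIAL_CHARGES`` data field is
    required per record) or ``"compute"`` (Gasteiger charges as a fallback
    when the upstream force-field assignment is unavailable).  CoMSIA
    property weights come from ``property_table`` (element -> (hydrophobicity,
    HBD, HBA)); untyped elements get all zeros.
    """
    table = DEFAULT_PROPERTY_TABLE if property_table is None else property_table
    with open(path) as fh:
        if not fh.read().strip():
            warnings.warn(f"{path}: empty SDF, no molecules read")
            return []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mols: list[AlignedMolecule] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"record {idx}: unparsable SDF record")
        mols.append(_mol_to_aligned(mol, idx, charge_policy, table))
    if not mols:
        warnings.warn(f"{path}: empty SDF, no molecules read")
    ids = [m.id for m in mols]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids in SDF set")
    return mols


def write_aligned_sdf(mols: list[AlignedMolecule], path) -> None:
    """Write molecules as V2000 SDF records (atoms only, no bonds),
    with charges in the ``PARTIAL_CHARGES`` field."""
    with open(path, "w") as fh:
        for m in mols:
            rw = Chem.RWMol()
            conf = Chem.Conformer(len(m.atoms))
            for i, a in enumerate(m.atoms):
                rw.AddAtom(Chem.Atom(a.element))
                conf.SetAtomPosition(i, a.position.tolist())
            conf.Set3D(True)
            mol = rw.GetMol()
            mol.AddConformer(conf)
            mol.SetProp("_Name", m.id)
            mol.SetProp(CHARGE_TAG,
                        "\n".join(f"{a.partial_charge:.10f}" for a in m.atoms))
            for atom in mol.GetAtoms():
                atom.SetNoImplicit(True)
            fh.write(Chem.MolToMolBlock(mol, kekulize=False))
            fh.write(f">  <{CHARGE_TAG}>\n{mol.GetProp(CHARGE_TAG)}\n\n$$$$\n")


def read_activity_csv(path) -> list[ActivityRecord]:
    """Activity table: columns compound_id, ic50_uM and/or pic50, subset."""
    df = pd.read_csv(path)
    if "compound_id" not in df.columns:
        raise ValueError("activity table needs a compound_id column")
    records = []
    for _, row in df.iterrows():
        ic50 = row.get("ic50_uM")
        pic50 = row.get("pic50")
        records.append(ActivityRecord(
            compound_id=str(row["compound_id"]),
            ic50=None if pd.isna(ic50) else float(ic50),
            pic50=None if pd.isna(pic50) else float(pic50),
            subset=str(row.get("subset", "train")),
        ))
    ids = [r.compound_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids in activity table")
    return records


def write_activity_csv(records: list[ActivityRecord], path) -> None:
    pd.DataFrame([{
        "compound_id": r.compound_id,
        "ic50_uM": r.ic50,
        "pic50": r.pic50,
        "subset": r.subset,
    } for r in records]).to_csv(path, index=False)


def read_cytotox_csv(path) -> list[CytotoxRecord]:
    """Cytotoxicity table: compound_id, cell_line, gi50_uM, censored."""
    df = pd.read_csv(path)
    return [CytotoxRecord(str(r.compound_id), str(r.cell_line),
                          float(r.gi50_uM), bool(getattr(r, "censored", False)))
            for r in df.itertuples(index=False)]
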