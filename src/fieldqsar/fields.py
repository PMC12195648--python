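"""Lattice construction and CoMFA/CoMSIA molecular-field descriptors.

CoMFA samples probe-atom interaction energies (Lennard-Jones 6-12 steric,
Coulomb electrostatic with distance-dependent dielectric) on a rectilinear
lattice; CoMSIA samples Gaussian-attenuated similarity indices for steric,
electrostatic, hydrophobic and H-bond donor/acceptor properties.  Each
compound's fields are flattened into one row of a :class:`FieldMatrix`,
which is then variance-filtered and block-scaled before PLS.

Functional forms:

  steric       E(q)  =  sum_i  eps_ip [ (r*_ip/r_iq)^12 - 2 (r*_ip/r_iq)^6 ],
               r*_ip = R_vdw,i + R_probe, eps_ip = sqrt(eps_i eps_probe),
               truncated above at the energy cutoff (default 30 kcal/mol)
  Coulomb      E(q)  =  332.0636 q_i q_probe / (D(r) r),  D(r) = r,
               clamped to +-cutoff
  similarity   A(q)  = -sum_i  w_probe w_i exp(-alpha r_iq^2),  alpha 0.3 1/A^2

The negative-similarity sign convention fixes A = -1 for a unit-weight atom
coincident with the probe.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .molecules import AlignedMolecule

COULOMB_CONSTANT = 332.0636  # kcal A / (mol e^2)

COMFA_FIELDS = ("S", "E")
COMSIA_FIELDS = ("S", "E", "H", "D", "A")


@dataclass(frozen=True)
class Lattice:
    """Axis-aligned rectilinear grid of probe positions."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if not self.spacing > 0:
            raise ValueError("lattice spacing must be > 0")
        if any(d < 1 for d in self.dims):
            raise ValueError("lattice dims must be positive")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def points(self) -> np.ndarray:
        """All lattice points, shape (n_points, 3), x fastest-varying last
        (C order over (ix, iy, iz))."""
        axes = [np.asarray(self.origin)[k] + self.spacing * np.arange(self.dims[k])
                for k in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        return grid.reshape(-1, 3)

    def contains(self, coords: np.ndarray) -> bool:
        lo = np.asarray(self.origin)
        hi = lo + self.spacing * (np.asarray(self.dims) - 1)
        return bool(np.all(coords >= lo - 1e-9) and np.all(coords <= hi + 1e-9))


@dataclass
class ProbeSpec:
    """Probe atom placed at each lattice point.

    CoMFA default: sp3 carbon, R = 1.52 A, charge +1.
    CoMSIA default: R = 1 A, charge +1, all similarity weights +1.
    """

    kind: str  # "comfa" | "comsia"
    radius: float
    charge: float = 1.0
    steric_eps: float = 0.1  # kcal/mol well depth
    hydrophobicity: float = 1.0
    hbd: float = 1.0
    hba: float = 1.0

    def __post_init__(self):
        if self.kind not in ("comfa", "comsia"):
            raise ValueError("probe kind must be 'comfa' or 'comsia'")
        if not self.radius > 0:
            raise ValueError("probe radius must be > 0")

    def comsia_weight(self, label: str) -> float:
        return {"S": self.radius ** 3, "E": self.charge,
                "H": self.hydrophobicity, "D": self.hbd, "A": self.hba}[label]


def comfa_probe() -> ProbeSpec:
    return ProbeSpec(kind="comfa", radius=1.52, charge=1.0)


def comsia_probe() -> ProbeSpec:
    return ProbeSpec(kind="comsia", radius=1.0, charge=1.0)


@dataclass
class FieldConfig:
    """Numerical knobs of field generation and descriptor filtering."""

    energy_cutoff: float = 30.0       # kcal/mol, CoMFA truncation
    attenuation_alpha: float = 0.3    # 1/A^2, CoMSIA Gaussian
    column_filter_sigma: float = 2.0  # min column sd retained (block units)
    fields_enabled: tuple[str, ...] = ("S", "E")
    atom_eps: dict = field(default_factory=dict)   # per-element LJ well depth
    default_atom_eps: float = 0.1                  # kcal/mol
    electrostatic_inside_policy: str = "column-mean"  # or "clamp"

    def __post_init__(self):
        if not self.energy_cutoff > 0:
            raise ValueError("energy_cutoff must be > 0")
        if not self.attenuation_alpha > 0:
            raise ValueError("attenuation_alpha must be > 0")
        for f in self.fields_enabled:
            if f not in COMSIA_FIELDS:
                raise ValueError(f"unknown field label {f!r}")

    def eps_for(self, elements) -> np.ndarray:
        return np.array([self.atom_eps.get(e, self.default_atom_eps)
                         for e in elements])


def build_lattice(molecules: list[AlignedMolecule], spacing: float = 2.0,
                  margin: float = 4.0) -> Lattice:
    """Smallest lattice whose box covers every atom of every molecule,
    expanded by ``margin`` on each side."""
    if not molecules:
        raise ValueError("cannot build a lattice from an empty molecule set")
    if not spacing > 0:
        raise ValueError("spacing must be > 0")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    coords = np.vstack([m.coords for m in molecules])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    dims = tuple(int(np.ceil((hi[k] - lo[k]) / spacing - 1e-9)) + 1 for k in range(3))
    return Lattice(origin=tuple(lo), spacing=spacing, dims=dims)


def _distances(mol: AlignedMolecule, lattice: Lattice) -> np.ndarray:
    return cdist(lattice.points(), mol.coords)  # (P, A)


def comfa_steric(mol: AlignedMolecule, lattice: Lattice, probe: ProbeSpec,
                 cfg: FieldConfig) -> np.ndarray:
    """Lennard-Jones 6-12 probe energy per lattice point, kcal/mol,
    truncated above at the cutoff (repulsive wall only)."""
    if probe.kind != "comfa":
        raise ValueError("comfa_steric requires a comfa probe")
    r = np.maximum(_distances(mol, lattice), 1e-3)
    rstar = mol.vdw_radii + probe.radius
    eps = np.sqrt(cfg.eps_for([a.element for a in mol.atoms]) * probe.steric_eps)
    sr6 = (rstar / r) ** 6
    e = (eps * (sr6 * sr6 - 2.0 * sr6)).sum(axis=1)
    return np.minimum(e, cfg.energy_cutoff)


def comfa_electrostatic(mol: AlignedMolecule, lattice: Lattice, probe: ProbeSpec,
                        cfg: FieldConfig) -> np.ndarray:
    """Coulomb probe energy with distance-dependent dielectric D(r) = r,
    kcal/mol, clamped to +-cutoff.

    The inside-molecule replacement (steric-capped points take the column
    mean over uncapped compounds) is a set-level operation applied in
    :func:`assemble_fields`.
    """
    if probe.kind != "comfa":
        raise ValueError("comfa_electrostatic requires a comfa probe")
    r = np.maximum(_distances(mol, lattice), 1e-3)
    e = (COULOMB_CONSTANT * probe.charge * mol.charges / (r * r)).sum(axis=1)
    return np.clip(e, -cfg.energy_cutoff, cfg.energy_cutoff)


def comsia_field(mol: AlignedMolecule, lattice: Lattice, prop: str,
                 probe: ProbeSpec, cfg: FieldConfig) -> np.ndarray:
    """Gaussian-attenuated similarity index per lattice point (dimensionless,
    negative-similarity convention).  Steric atom weight is R_vdw^3,
    electrostatic weight the partial charge, H/D/A from the typing table."""
    if probe.kind != "comsia":
        raise ValueError("comsia_field requires a comsia probe")
    w = mol.property_weights(prop)  # raises on unknown label
    r2 = _distances(mol, lattice) ** 2
    return -(probe.comsia_weight(prop)
             * (w * np.exp(-cfg.attenuation_alpha * r2)).sum(axis=1))


@dataclass
class FieldMatrix:
    """Compounds x (lattice point, field label) descriptor block.

    ``values`` holds raw field values; modeling consumes the masked,
    block-scaled view from :meth:`modeling_matrix`.  Column metadata keeps
    enough to map any column back to a 3D lattice position.
    """

    values: np.ndarray                 # (n_compounds, n_columns)
    compound_ids: list[str]
    field_labels: np.ndarray           # (n_columns,) e.g. "comfa:S"
    point_indices: np.ndarray          # (n_columns,) flat lattice index
    lattice: Lattice
    method: str                        # "comfa" | "comsia"
    block_scale: dict = field(default_factory=dict)   # label -> factor
    column_mask: np.ndarray | None = None             # retained columns

    def __post_init__(self):
        if self.column_mask is None:
            self.column_mask = np.ones(self.values.shape[1], dtype=bool)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field matrix contains non-finite values")

    @property
    def blocks(self) -> list[str]:
        seen: list[str] = []
        for lbl in self.field_labels:
            if lbl not in seen:
                seen.append(lbl)
        return seen

    def block_columns(self, label: str) -> np.ndarray:
        return np.where(self.field_labels == label)[0]

    def scale_vector(self) -> np.ndarray:
        return np.array([self.block_scale.get(lbl, 1.0) for lbl in self.field_labels])

    def modeling_matrix(self) -> np.ndarray:
        """Retained columns, divided by their block scale factor."""
        return self.values[:, self.column_mask] / self.scale_vector()[self.column_mask]

    def retained_indices(self) -> np.ndarray:
        return np.where(self.column_mask)[0]

    def subset_rows(self, mask) -> "FieldMatrix":
        """Restrict to the compounds selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        return replace(self, values=self.values[mask],
                       compound_ids=[c for c, m in zip(self.compound_ids, mask) if m])

    def subset_fields(self, labels) -> "FieldMatrix":
        """Restrict to the blocks whose bare field letter is in ``labels``."""
        letters = set(labels)
        keep = np.array([lbl.split(":")[-1] in letters for lbl in self.field_labels])
        if not keep.any():
            raise ValueError(f"no columns for fields {sorted(letters)}")
        return FieldMatrix(
            values=self.values[:, keep],
            compound_ids=self.compound_ids,
            field_labels=self.field_labels[keep],
            point_indices=self.point_indices[keep],
            lattice=self.lattice,
            method=self.method,
            block_scale=dict(self.block_scale),
            column_mask=self.column_mask[keep],
        )


def assemble_fields(molecules: list[AlignedMolecule], lattice: Lattice,
                    cfg: FieldConfig, method: str = "comfa",
                    probe: ProbeSpec | None = None) -> FieldMatrix:
    """Compute every enabled field for every molecule and stack the rows.

    Per-block scale factors (pooled standard deviation of the centered block,
    the CoMFA-STD convention) are recorded so no block dominates the PLS.
    """
    if method not in ("comfa", "comsia"):
        raise ValueError("method must be 'comfa' or 'comsia'")
    valid = COMFA_FIELDS if method == "comfa" else COMSIA_FIELDS
    labels = [f for f in cfg.fields_enabled if f in valid]
    if not labels:
        raise ValueError(f"no enabled fields valid for method {method!r}")
    if probe is None:
        probe = comfa_probe() if method == "comfa" else comsia_probe()
    for m in molecules:
        if not lattice.contains(m.coords):
            raise ValueError(f"molecule {m.id!r} extends outside the lattice")

    n_pts = lattice.n_points
    blocks: dict[str, np.ndarray] = {}
    if method == "comfa":
        steric = np.vstack([comfa_steric(m, lattice, probe, cfg) for m in molecules])
        if "S" in labels:
            blocks["S"] = steric
        if "E" in labels:
            ele = np.vstack([comfa_electrostatic(m, lattice, probe, cfg)
                             for m in molecules])
            if cfg.electrostatic_inside_policy == "column-mean":
                capped = steric >= cfg.energy_cutoff - 1e-9
                for j in range(n_pts):
                    c = capped[:, j]
                    if c.any():
                        ele[c, j] = ele[~c, j].mean() if (~c).any() else 0.0
            blocks["E"] = ele
    else:
        for lbl in labels:
            blocks[lbl] = np.vstack([comsia_field(m, lattice, lbl, probe, cfg)
                                     for m in molecules])

    values = np.hstack([blocks[lbl] for lbl in labels])
    field_labels = np.concatenate(
        [np.full(n_pts, f"{method}:{lbl}") for lbl in labels])
    point_indices = np.concatenate([np.arange(n_pts) for _ in labels])

    scales = {}
    for lbl in labels:
        block = blocks[lbl]
        sd = float(np.std(block - block.mean(axis=0), ddof=0))
        scales[f"{method}:{lbl}"] = sd if sd > 0 else 1.0

    return FieldMatrix(values=values, compound_ids=[m.id for m in molecules],
                       field_labels=field_labels, point_indices=point_indices,
                       lattice=lattice, method=method, block_scale=scales)


def column_filter(fm: FieldMatrix, sigma: float | None = None) -> FieldMatrix:
    """Mask columns whose standard deviation across compounds falls below
    ``sigma`` (in the block's native units).  Masked columns stay in the
    matrix for contour export; only modeling ignores them."""
    if sigma is None:
        sigma = 2.0
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    sds = fm.values.std(axis=0, ddof=1) if fm.values.shape[0] > 1 \
        else np.zeros(fm.values.shape[1])
    mask = np.ones(fm.values.shape[1], dtype=bool) if sigma == 0 else (sds >= sigma)
    if sigma > 0 and not mask.any():
        warnings.warn("column filter removed every column")
    return replace(fm, column_mask=mask)


def write_dx(path, lattice: Lattice, values: np.ndarray, comment: str = "") -> None:
    """Write one scalar lattice field as an OpenDX grid (.dx)."""
    v = np.asarray(values, dtype=float).reshape(-1)
    if v.size != lattice.n_points:
        raise ValueError("value vector does not match lattice size")
    nx, ny, nz = lattice.dims
    d = lattice.spacing
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*lattice.origin))
        fh.write(f"delta {d:.6f} 0 0\ndelta 0 {d:.6f} 0\ndelta 0 0 {d:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {v.size} data follows\n")
        for i in range(0, v.size, 3):
            fh.write(" ".join(f"{x:.6e}" for x in v[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n'
                 'object "field" class field\n'
                 'component "positions" value 1\n'
                 'component "connections" value 2\n'
                 'component "data" value 3\n')


def write_cube(path, lattice: Lattice, values: np.ndarray, comment: str = "") -> None:
    """Write one scalar lattice field as a Gaussian cube file (grid in
    Angstrom, converted to Bohr as the format requires)."""
    bohr = 1.0 / 0.529177210903
    v = np.asarray(values, dtype=float).reshape(lattice.dims)
    nx, ny, nz = lattice.dims
    d = lattice.spacing * bohr
    o = np.asarray(lattice.origin) * bohr
    with open(path, "w") as fh:
        fh.write(f"fieldqsar cube export\n{comment}\n")
        fh.write(f"{1:5d} {o[0]:12.6f} {o[1]:12.6f} {o[2]:12.6f}\n")
        fh.write(f"{nx:5d} {d:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {d:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {d:12.6f}\n")
        fh.write(f"{6:5d} {0.0:12.6f} {o[0]:12.6f} {o[1]:12.6f} {o[2]:12.6f}\n")
        for ix, iy in itertools.product(range(nx), range(ny)):
            row = v[ix, iy, :]
            for i in range(0, nz, 6):
                fh.write("".join(f"{x:13.5e}" for x in row[i:i + 6]) + "\n")


def save_field_matrix(fm: FieldMatrix, basepath) -> None:
    """Round-trip a FieldMatrix as <base>.npz + <base>.json metadata."""
    basepath = str(basepath)
    np.savez_compressed(basepath + ".npz", values=fm.values,
                        point_indices=fm.point_indices,
                        column_mask=fm.column_mask,
                        field_labels=np.asarray(fm.field_labels, dtype="U"))
    meta = {
        "compound_ids": fm.compound_ids,
        "method": fm.method,
        "block_scale": fm.block_scale,
        "lattice": {"origin": list(fm.lattice.origin),
                    "spacing": fm.lattice.spacing,
                    "dims": list(fm.lattice.dims)},
    }
    with open(basepath + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_field_matrix(basepath) -> FieldMatrix:
    basepath = str(basepath)
    arrays = np.load(basepath + ".npz")
    with open(basepath + ".json") as fh:
        meta = json.load(fh)
    lat = Lattice(origin=tuple(meta["lattice"]["origin"]),
                  spacing=meta["lattice"]["spacing"],
                  dims=tuple(meta["lattice"]["dims"]))
    return FieldMatrix(values=arrays["values"],
                       compound_ids=list(meta["compound_ids"]),
                       field_labels=arrays["field_labels"],
                       point_indices=arrays["point_indices"],
                       lattice=lat, method=meta["method"],
                       block_scale=meta["block_scale"],
                       column_mask=arrays["column_mask"])
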