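"""Molecule and activity I/O, unit conversion, and rigid template alignment.

Molecules are read from SDF/MOL (V2000/V3000) files.  Partial charges are
taken from a per-record SDF property (default ``PARTIAL_CHARGES``, one
whitespace- or comma-separated value per atom) when present, otherwise
Gasteiger charges are computed.  Van der Waals parameters come from a
packaged element table (Tripos-5.2-like values) and may be overridden.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

DEFAULT_CHARGE_PROPERTY = "PARTIAL_CHARGES"

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}


@dataclass(frozen=True)
class Atom:
    """A single atom: element, Cartesian position (Å), partial charge (e),
    and Lennard-Jones parameters (rmin in Å, epsilon in kcal/mol)."""

    element: str
    position: np.ndarray
    partial_charge: float = 0.0
    vdw_rmin: float = 1.70
    vdw_epsilon: float = 0.107

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if self.vdw_rmin <= 0:
            raise ValueError(f"vdw_rmin must be > 0, got {self.vdw_rmin}")
        if self.vdw_epsilon < 0:
            raise ValueError(f"vdw_epsilon must be >= 0, got {self.vdw_epsilon}")


@dataclass
class Molecule:
    """A named 3D structure as an ordered list of atoms."""

    id: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    pIC50: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.pIC50):
            raise ValueError(f"pIC50 for {self.compound_id!r} is not finite")


@dataclass
class TemplateMap:
    """Correspondence between template atoms of a reference molecule and
    matched atoms of each molecule in the series.

    ``template_atom_indices`` index into the reference molecule; for every
    molecule id, ``matched_indices[mol_id]`` lists the same number of atom
    indices in that molecule, in corresponding order.
    """

    template_atom_indices: list[int]
    matched_indices: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.template_atom_indices) < 3:
            raise ValueError("template map needs >= 3 mapped atoms")
        for mol_id, idx in self.matched_indices.items():
            if len(idx) != len(self.template_atom_indices):
                raise ValueError(f"map for {mol_id!r} has wrong length")
            if len(set(idx)) != len(idx):
                raise ValueError(f"map for {mol_id!r} is not injective")


def load_vdw_table(path: str | Path | None = None) -> dict[str, tuple[float, float]]:
    """Load the element -> (rmin, epsilon) table; packaged defaults if no path."""
    if path is None:
        source = resources.files("gridqsar.data").joinpath("vdw_params.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, tuple[float, float]] = {}
    for row in csv.DictReader(text.splitlines()):
        table[row["element"]] = (float(row["rmin"]), float(row["epsilon"]))
    return table


def _charges_from_property(mol: Chem.Mol, prop: str) -> np.ndarray | None:
    if not mol.HasProp(prop):
        return None
    raw = mol.GetProp(prop).replace(",", " ").split()
    values = np.array([float(v) for v in raw], dtype=float)
    if len(values) != mol.GetNumAtoms():
        raise ValueError(
            f"property {prop!r} has {len(values)} values for {mol.GetNumAtoms()} atoms"
        )
    return values


def _gasteiger_charges(mol: Chem.Mol) -> np.ndarray:
    AllChem.ComputeGasteigerCharges(mol)
    q = np.array(
        [a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()], dtype=float
    )
    # Gasteiger can produce NaN for exotic atoms; zero them rather than poison fields.
    return np.nan_to_num(q, nan=0.0)


def read_molecules(
    path: str | Path,
    charge_property: str = DEFAULT_CHARGE_PROPERTY,
    vdw_table: Mapping[str, tuple[float, float]] | None = None,
) -> list[Molecule]:
    """Read an SDF/MOL file into a list of :class:`Molecule`.

    Hydrogens are kept as supplied.  Raises ``ValueError`` naming the record
    index on an unparseable record, and naming the element if it is missing
    from the vdW table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if vdw_table is None:
        vdw_table = load_vdw_table()
    if not path.read_text().strip():
        logger.warning("no records found in %s", path)
        return []

    supplier = Chem.SDMolSupplier(
        str(path), removeHs=False, sanitize=False, strictParsing=False
    )
    molecules: list[Molecule] = []
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ValueError(f"unparseable SDF record at index {i} in {path}")
        try:
            Chem.SanitizeMol(rdmol, catchErrors=False)
        except Exception:
            # fall back to partial sanitization; geometry and elements suffice
            rdmol.UpdatePropertyCache(strict=False)
        if rdmol.GetNumConformers() == 0:
            raise ValueError(f"record {i} in {path} has no 3D coordinates")
        name = rdmol.GetProp("_Name").strip() if rdmol.HasProp("_Name") else ""
        mol_id = name or f"mol_{i}"
        charges = _charges_from_property(rdmol, charge_property)
        if charges is None:
            charges = _gasteiger_charges(rdmol)
        conf = rdmol.GetConformer()
        atoms = []
        for j, a in enumerate(rdmol.GetAtoms()):
            symbol = a.GetSymbol()
            if symbol not in vdw_table:
                raise ValueError(f"no vdW parameters for {symbol}")
            rmin, eps = vdw_table[symbol]
            p = conf.GetAtomPosition(j)
            atoms.append(
                Atom(
                    element=symbol,
                    position=np.array([p.x, p.y, p.z]),
                    partial_charge=float(charges[j]),
                    vdw_rmin=rmin,
                    vdw_epsilon=eps,
                )
            )
        molecules.append(Molecule(id=mol_id, atoms=atoms))
    if not molecules:
        logger.warning("no records found in %s", path)
    ids = [m.id for m in molecules]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate molecule ids in {path}")
    return molecules


def write_molecules(
    molecules: Iterable[Molecule],
    path: str | Path,
    charge_property: str = DEFAULT_CHARGE_PROPERTY,
) -> None:
    """Write molecules to SDF, preserving coordinates and partial charges.

    Connectivity is not tracked by :class:`Molecule`; records are written as
    disconnected atom blocks, which round-trips elements, coordinates and
    charges (the quantities the field engine consumes).
    """
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for mol in molecules:
        rw = Chem.RWMol()
        conf = Chem.Conformer(mol.n_atoms)
        for j, atom in enumerate(mol.atoms):
            a = Chem.Atom(atom.element)
            a.SetNoImplicit(True)
            rw.AddAtom(a)
            conf.SetAtomPosition(j, atom.position.tolist())
        out = rw.GetMol()
        out.AddConformer(conf)
        out.SetProp("_Name", mol.id)
        out.SetProp(charge_property, " ".join(f"{a.partial_charge:.6f}" for a in mol.atoms))
        out.UpdatePropertyCache(strict=False)
        writer.write(out)
    writer.close()


def to_pic50(ic50_value: float, unit: str = "M") -> float:
    """Convert an IC50 in the given unit (M, mM, uM/µM, nM) to pIC50."""
    if unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unknown concentration unit {unit!r}")
    if ic50_value <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_value}")
    return -math.log10(ic50_value * _UNIT_TO_MOLAR[unit])


def read_activities(path: str | Path) -> list[ActivityRecord]:
    """Read an activity CSV with header ``compound_id,pIC50`` or
    ``compound_id,value,unit`` (converted via :func:`to_pic50`)."""
    records: list[ActivityRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fields = set(reader.fieldnames or ())
        if {"compound_id", "pIC50"} <= fields:
            for row in reader:
                records.append(ActivityRecord(row["compound_id"], float(row["pIC50"])))
        elif {"compound_id", "value", "unit"} <= fields:
            for row in reader:
                records.append(
                    ActivityRecord(row["compound_id"], to_pic50(float(row["value"]), row["unit"]))
                )
        else:
            raise ValueError(
                "activity CSV must have columns (compound_id,pIC50) or (compound_id,value,unit)"
            )
    seen = [r.compound_id for r in records]
    if len(set(seen)) != len(seen):
        raise ValueError("duplicate compound_id in activity table")
    return records


def write_activities(records: Iterable[ActivityRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "pIC50"])
        for r in records:
            writer.writerow([r.compound_id, f"{r.pIC50:.6f}"])


def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition: rotation R and translation t with
    ``moving @ R.T + t ≈ target``.  Reflections are excluded."""
    mc = moving.mean(axis=0)
    tc = target.mean(axis=0)
    a = moving - mc
    b = target - tc
    # collinear/degenerate point sets leave the rotation underdetermined
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValueError("mapped atoms are collinear or degenerate; cannot align")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = tc - rot @ mc
    return rot, trans


def align_to_template(
    mol: Molecule, reference: Molecule, template_map: TemplateMap
) -> tuple[Molecule, float]:
    """Rigidly transform ``mol`` onto ``reference`` over the mapped atoms.

    Returns the transformed molecule and the post-fit RMSD (Å) over the
    mapped atoms.  The transform is rotation + translation only, so all
    intramolecular distances are preserved.
    """
    ref_idx = template_map.template_atom_indices
    if mol.id not in template_map.matched_indices:
        raise KeyError(f"template map has no entry for molecule {mol.id!r}")
    mol_idx = template_map.matched_indices[mol.id]
    target = reference.coordinates()[ref_idx]
    moving_all = mol.coordinates()
    moving = moving_all[mol_idx]
    rot, trans = kabsch(moving, target)
    new_coords = moving_all @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((new_coords[mol_idx] - target) ** 2, axis=1))))
    new_atoms = [replace(a, position=new_coords[j]) for j, a in enumerate(mol.atoms)]
    return Molecule(id=mol.id, atoms=new_atoms), rmsd


def align_series(
    molecules: Sequence[Molecule], reference_id: str, template_map: TemplateMap
) -> tuple[list[Molecule], dict[str, float]]:
    """Align every molecule of a series to the named reference. Returns the
    aligned series (reference untouched) and per-molecule RMSDs."""
    by_id = {m.id: m for m in molecules}
    if reference_id not in by_id:
        raise KeyError(f"reference molecule {reference_id!r} not in series")
    reference = by_id[reference_id]
    aligned: list[Molecule] = []
    rmsds: dict[str, float] = {}
    for mol in molecules:
        if mol.id == reference_id:
            aligned.append(mol)
            rmsds[mol.id] = 0.0
        else:
            new_mol, rmsd = align_to_template(mol, reference, template_map)
            aligned.append(new_mol)
            rmsds[mol.id] = rmsd
    return aligned, rmsds
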