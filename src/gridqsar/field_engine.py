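"""Rectangular-grid probe interaction fields (steric Lennard-Jones and
electrostatic Coulomb energies) around aligned molecules.

Conventions (all overridable):

* grid spacing 2.0 Å, margin 4.0 Å around the union bounding box;
* probe = sp3 carbon: rmin 1.70 Å, epsilon 0.107 kcal/mol, charge +1 e;
* steric energies clamped to +30 kcal/mol, electrostatic to ±30 kcal/mol;
* constant dielectric D0 = 1 by default (``distance`` selects D = D0·r);
* the Lennard-Jones minimum distance is R_ij = rmin_atom + rmin_probe
  (arithmetic combination of per-atom rmin parameters);
* grid points are enumerated x-fastest, 1-based, giving descriptor names
  ``S_<i>`` and ``E_<i>``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .chem_io import Molecule

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)

DEFAULT_SPACING = 2.0
DEFAULT_MARGIN = 4.0
DEFAULT_STERIC_CUTOFF = 30.0
DEFAULT_ELEC_CUTOFF = 30.0

DielectricModel = Literal["constant", "distance"]


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned rectangular grid: origin (Å), uniform spacing (Å), and
    point counts per axis."""

    origin: tuple[float, float, float]
    spacing: float
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if any(c < 1 for c in self.counts):
            raise ValueError("grid counts must each be >= 1")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """(n_points, 3) array of grid-point coordinates, x varying fastest."""
        ox, oy, oz = self.origin
        nx, ny, nz = self.counts
        xs = ox + self.spacing * np.arange(nx)
        ys = oy + self.spacing * np.arange(ny)
        zs = oz + self.spacing * np.arange(nz)
        zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def provenance_hash(self) -> str:
        """Stable hash of the grid geometry, used to guard descriptor identity
        across datasets."""
        payload = json.dumps(
            {
                "origin": [round(v, 9) for v in self.origin],
                "spacing": round(self.spacing, 9),
                "counts": list(self.counts),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "spacing": self.spacing,
            "counts": list(self.counts),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            origin=tuple(float(v) for v in d["origin"]),
            spacing=float(d["spacing"]),
            counts=tuple(int(v) for v in d["counts"]),
        )


@dataclass(frozen=True)
class ProbeSpec:
    """Probe atom parameters; default is an sp3 carbon with unit positive charge."""

    vdw_rmin: float = 1.70
    vdw_epsilon: float = 0.107
    charge: float = 1.0

    def __post_init__(self) -> None:
        if self.vdw_rmin <= 0:
            raise ValueError("probe vdw_rmin must be > 0")
        if self.vdw_epsilon < 0:
            raise ValueError("probe vdw_epsilon must be >= 0")


def build_grid(
    molecules: Sequence[Molecule],
    spacing: float = DEFAULT_SPACING,
    margin: float = DEFAULT_MARGIN,
) -> GridSpec:
    """Grid spanning [min − margin, max + margin] per axis over all atoms of
    all molecules, with counts = floor(span/spacing) + 1."""
    if not molecules:
        raise ValueError("need at least one molecule to build a grid")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    coords = np.vstack([m.coordinates() for m in molecules])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    span = hi - lo
    # tiny epsilon so an exact multiple of the spacing keeps its endpoint
    counts = tuple(int(np.floor(s / spacing + 1e-9)) + 1 for s in span)
    return GridSpec(origin=tuple(float(v) for v in lo), spacing=float(spacing), counts=counts)


def _distances(points: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """(n_points, n_atoms) Euclidean distance matrix."""
    diff = points[:, None, :] - coords[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def steric_field(
    mol: Molecule,
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    cutoff: float = DEFAULT_STERIC_CUTOFF,
) -> np.ndarray:
    """Lennard-Jones probe energy at every grid point, kcal/mol.

    E(p) = Σ_atoms ε_ij [(R_ij/r)^12 − 2 (R_ij/r)^6], ε_ij = √(ε_a ε_p),
    R_ij = rmin_a + rmin_p; the per-point sum is clamped to +cutoff, and a
    probe exactly on a nucleus reports the cutoff.
    """
    points = grid.points()
    coords = mol.coordinates()
    rmin = np.array([a.vdw_rmin for a in mol.atoms]) + probe.vdw_rmin
    eps = np.sqrt(np.array([a.vdw_epsilon for a in mol.atoms]) * probe.vdw_epsilon)
    r = _distances(points, coords)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        ratio6 = (rmin[None, :] / r) ** 6
        energy = eps[None, :] * (ratio6 * ratio6 - 2.0 * ratio6)
        energy = np.where(r == 0.0, np.inf, energy)
    total = np.sum(np.nan_to_num(energy, posinf=np.inf), axis=1)
    return np.minimum(total, cutoff)


def electrostatic_field(
    mol: Molecule,
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    dielectric_model: DielectricModel = "constant",
    dielectric_constant: float = 1.0,
    cutoff: float = DEFAULT_ELEC_CUTOFF,
) -> np.ndarray:
    """Coulomb probe energy at every grid point, kcal/mol.

    E(p) = Σ_atoms 332.0636 q_a q_p / (D(r) r) with D(r) = D0 or D0·r; the
    per-point sum is clamped to ±cutoff and r = 0 contributes the (signed)
    cutoff rather than a division error.
    """
    if dielectric_model not in ("constant", "distance"):
        raise ValueError(f"unknown dielectric model {dielectric_model!r}")
    points = grid.points()
    coords = mol.coordinates()
    q = mol.charges()
    r = _distances(points, coords)
    denom = dielectric_constant * (r * r if dielectric_model == "distance" else r)
    with np.errstate(divide="ignore", invalid="ignore"):
        energy = COULOMB_CONSTANT * q[None, :] * probe.charge / denom
        energy = np.where(r == 0.0, np.sign(q[None, :] * probe.charge) * np.inf, energy)
    total = np.sum(np.nan_to_num(energy, posinf=np.inf, neginf=-np.inf), axis=1)
    return np.clip(total, -cutoff, cutoff)


def descriptor_names(grid: GridSpec) -> list[str]:
    """Column names: the steric block then the electrostatic block, each in
    1-based grid-index order (x fastest)."""
    n = grid.n_points
    return [f"S_{i}" for i in range(1, n + 1)] + [f"E_{i}" for i in range(1, n + 1)]
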