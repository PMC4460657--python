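"""Compound × grid-field descriptor matrix: assembly, naming, invariable-column
removal, and CSV round trips with grid provenance."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_io import Molecule
from .field_engine import (
    DielectricModel,
    GridSpec,
    ProbeSpec,
    descriptor_names,
    electrostatic_field,
    steric_field,
)

logger = logging.getLogger(__name__)

DEFAULT_INVARIABLE_TOL = 1e-8


@dataclass
class FieldDescriptorMatrix:
    """A rectangular table of field descriptors (kcal/mol): rows = compound
    ids, columns = descriptor names (``S_i`` then ``E_i``), plus the grid
    provenance hash the descriptors were computed on."""

    data: pd.DataFrame
    grid: GridSpec | None = None
    grid_hash: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate compound ids in descriptor matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate descriptor names in descriptor matrix")
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ValueError("descriptor matrix contains non-finite values")
        if self.grid is not None and not self.grid_hash:
            self.grid_hash = self.grid.provenance_hash()

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write the matrix as wide CSV; grid metadata goes to a JSON sidecar
        (default ``<path>.grid.json``)."""
        path = Path(path)
        self.data.to_csv(path, index_label="compound_id")
        meta = {"grid_hash": self.grid_hash}
        if self.grid is not None:
            meta["grid"] = self.grid.to_dict()
        sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".grid.json")
        sidecar.write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(
        cls, path: str | Path, sidecar: str | Path | None = None
    ) -> "FieldDescriptorMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col="compound_id")
        df.index = df.index.astype(str)
        df.index.name = None
        sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".grid.json")
        grid = None
        grid_hash = ""
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            grid_hash = meta.get("grid_hash", "")
            if "grid" in meta:
                grid = GridSpec.from_dict(meta["grid"])
        return cls(data=df, grid=grid, grid_hash=grid_hash)


def assemble(
    molecules: Sequence[Molecule],
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    dielectric_model: DielectricModel = "constant",
    dielectric_constant: float = 1.0,
) -> FieldDescriptorMatrix:
    """Compute the steric and electrostatic fields of every molecule on the
    shared grid; columns are all steric then all electrostatic descriptors,
    2 × n_grid_points in total."""
    names = descriptor_names(grid)
    rows = np.empty((len(molecules), len(names)))
    for i, mol in enumerate(molecules):
        s = steric_field(mol, grid, probe)
        e = electrostatic_field(
            mol, grid, probe, dielectric_model=dielectric_model,
            dielectric_constant=dielectric_constant,
        )
        rows[i] = np.concatenate([s, e])
    df = pd.DataFrame(rows, index=[m.id for m in molecules], columns=names)
    return FieldDescriptorMatrix(data=df, grid=grid)


def drop_invariable(
    matrix: FieldDescriptorMatrix, tol: float = DEFAULT_INVARIABLE_TOL
) -> FieldDescriptorMatrix:
    """Remove every column whose value range (max − min) is ≤ ``tol``,
    preserving the order of the survivors."""
    if matrix.data.empty:
        raise ValueError("descriptor matrix is empty")
    values = matrix.values()
    spread = values.max(axis=0) - values.min(axis=0)
    keep = spread > tol
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("no variable descriptors remain")
    logger.info(
        "drop_invariable: removed %d of %d columns (tol=%g)",
        n_removed, len(keep), tol,
    )
    return FieldDescriptorMatrix(
        data=matrix.data.loc[:, keep], grid=matrix.grid, grid_hash=matrix.grid_hash
    )


def autoscale(matrix: FieldDescriptorMatrix) -> np.ndarray:
    """Columns scaled to zero mean / unit variance; zero-variance columns map
    to zero rather than dividing by zero."""
    values = matrix.values()
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (values - mean) / sd_safe
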