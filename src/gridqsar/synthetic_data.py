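"""Seeded generators: congeneric molecule series (shared rigid scaffold +
variable substituents) and planted-truth descriptor/activity datasets for
exercising and benchmarking every pipeline stage offline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_io import ActivityRecord, Atom, Molecule, TemplateMap, load_vdw_table
from .descriptor_table import FieldDescriptorMatrix, assemble, drop_invariable
from .field_engine import ProbeSpec, build_grid

# rigid 9-atom scaffold loosely shaped like a fused bicyclic core (Å)
_SCAFFOLD = [
    ("C", (0.000, 0.000, 0.000)),
    ("C", (1.400, 0.000, 0.000)),
    ("C", (2.100, 1.212, 0.000)),
    ("N", (1.400, 2.425, 0.000)),
    ("C", (0.000, 2.425, 0.000)),
    ("C", (-0.700, 1.212, 0.000)),
    ("S", (3.800, 1.212, 0.000)),
    ("N", (-2.100, 1.212, 0.000)),
    ("C", (-2.800, 2.425, 0.100)),
]

_SUBSTITUENT_ELEMENTS = ["C", "N", "O", "F", "Cl", "S", "H"]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth behind a generated dataset: which descriptors carry the
    signal, their coefficients, the intercept, and the noise level."""

    informative: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if not self.informative:
            raise ValueError("informative set must be nonempty")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def make_series(n_compounds: int, seed: int) -> tuple[list[Molecule], TemplateMap]:
    """A congeneric series: every molecule shares the scaffold coordinates
    exactly (pre-aligned by construction) and carries 2–5 seeded substituent
    atoms with varying positions and charges."""
    if n_compounds < 2:
        raise ValueError("need at least 2 compounds")
    rng = np.random.default_rng(seed)
    vdw = load_vdw_table()
    molecules: list[Molecule] = []
    matched: dict[str, list[int]] = {}
    scaffold_idx = list(range(len(_SCAFFOLD)))
    for i in range(n_compounds):
        mol_id = f"cmpd_{i + 1:03d}"
        atoms = []
        for element, pos in _SCAFFOLD:
            rmin, eps = vdw[element]
            atoms.append(
                Atom(
                    element=element,
                    position=np.array(pos),
                    partial_charge=round(float(rng.normal(0.0, 0.15)), 4),
                    vdw_rmin=rmin,
                    vdw_epsilon=eps,
                )
            )
        n_sub = int(rng.integers(2, 6))
        for _ in range(n_sub):
            element = str(rng.choice(_SUBSTITUENT_ELEMENTS))
            rmin, eps = vdw[element]
            anchor = np.array(_SCAFFOLD[int(rng.integers(0, len(_SCAFFOLD)))][1])
            offset = rng.normal(0.0, 1.0, size=3)
            offset *= (1.4 + rng.uniform(0, 1.2)) / max(np.linalg.norm(offset), 1e-6)
            atoms.append(
                Atom(
                    element=element,
                    position=anchor + offset,
                    partial_charge=round(float(rng.normal(0.0, 0.25)), 4),
                    vdw_rmin=rmin,
                    vdw_epsilon=eps,
                )
            )
        molecules.append(Molecule(id=mol_id, atoms=atoms))
        matched[mol_id] = scaffold_idx
    template_map = TemplateMap(template_atom_indices=scaffold_idx, matched_indices=matched)
    return molecules, template_map


def make_planted_dataset(
    n_compounds: int = 40,
    n_descriptors: int = 50,
    k_informative: int = 3,
    coefficient_scale: float = 0.5,
    noise_sd: float = 0.2,
    seed: int = 0,
    constant_fraction: float = 0.03,
    correlated_fraction: float = 0.2,
    intercept: float = 5.0,
) -> tuple[FieldDescriptorMatrix, list[ActivityRecord], PlantedTruth]:
    """Descriptor matrix + activities with a sparse linear ground truth.

    The matrix mimics real field tables: a fraction of exactly constant
    columns (exercising invariable-column removal) and blocks of highly
    correlated columns (pairwise r ≈ 0.9, stressing selection tie-breaks).
    Activities are y = intercept + Σ β_j x_j + N(0, noise_sd).
    """
    if k_informative >= n_descriptors:
        raise ValueError("k_informative must be < n_descriptors")
    if n_compounds <= k_informative + 2:
        raise ValueError("n_compounds must exceed k_informative + 2")
    rng = np.random.default_rng(seed)

    n_constant = int(round(constant_fraction * n_descriptors))
    n_constant = min(n_constant, n_descriptors - k_informative - 1)
    x = rng.normal(0.0, 1.0, size=(n_compounds, n_descriptors))

    n_half = n_descriptors // 2
    names = [f"S_{i + 1}" for i in range(n_half)] + [
        f"E_{i + 1}" for i in range(n_descriptors - n_half)
    ]

    variable_idx = list(range(n_descriptors))
    # constant columns scattered through the matrix
    constant_idx = sorted(rng.choice(n_descriptors, size=n_constant, replace=False).tolist())
    for j in constant_idx:
        x[:, j] = float(rng.normal(0.0, 2.0))
        variable_idx.remove(j)

    informative_idx = sorted(
        rng.choice(variable_idx, size=k_informative, replace=False).tolist()
    )

    # correlated companions of non-informative variable columns
    pool = [j for j in variable_idx if j not in informative_idx]
    n_corr = min(int(round(correlated_fraction * n_descriptors)) // 2 * 2, len(pool) - 1)
    corr_pairs = rng.choice(pool, size=n_corr, replace=False).reshape(-1, 2) if n_corr >= 2 else []
    for a, b in corr_pairs:
        x[:, b] = 0.9 * x[:, a] + np.sqrt(1 - 0.9**2) * rng.normal(0.0, 1.0, n_compounds)

    betas = coefficient_scale * rng.uniform(0.5, 1.5, size=k_informative)
    betas *= rng.choice([-1.0, 1.0], size=k_informative)
    y = intercept + x[:, informative_idx] @ betas + rng.normal(0.0, noise_sd, n_compounds)

    ids = [f"cmpd_{i + 1:03d}" for i in range(n_compounds)]
    df = pd.DataFrame(x, index=ids, columns=names)
    matrix = FieldDescriptorMatrix(data=df, grid=None, grid_hash=f"synthetic-{seed}")
    activities = [ActivityRecord(cid, float(v)) for cid, v in zip(ids, y)]
    truth = PlantedTruth(
        informative=tuple(names[j] for j in informative_idx),
        coefficients={names[j]: float(b) for j, b in zip(informative_idx, betas)},
        intercept=intercept,
        noise_sd=noise_sd,
        seed=seed,
    )
    return matrix, activities, truth


def make_field_activity_series(
    n_compounds: int,
    seed: int,
    k_informative: int = 3,
    noise_sd: float = 0.2,
    spacing: float = 2.0,
    margin: float = 4.0,
    intercept: float = 5.0,
) -> tuple[list[Molecule], TemplateMap, list[ActivityRecord], PlantedTruth]:
    """A congeneric series whose activities truly follow a sparse linear model
    on its own grid-field descriptors (plus Gaussian noise).

    Descriptors are computed on the default grid, invariable columns dropped,
    and ``k_informative`` well-varying columns drive
    y = intercept + Σ β_j z_j + N(0, noise_sd) with z the autoscaled column.
    """
    molecules, template_map = make_series(n_compounds, seed)
    rng = np.random.default_rng(seed + 1)
    grid = build_grid(molecules, spacing=spacing, margin=margin)
    matrix = drop_invariable(assemble(molecules, grid, ProbeSpec()))
    values = matrix.values()
    sd = values.std(axis=0)
    candidates = np.flatnonzero(sd >= np.quantile(sd, 0.75))
    chosen = sorted(rng.choice(candidates, size=k_informative, replace=False).tolist())
    names = [matrix.descriptor_names[j] for j in chosen]
    z = (values[:, chosen] - values[:, chosen].mean(axis=0)) / sd[chosen]
    betas = rng.uniform(0.5, 1.5, size=k_informative) * rng.choice([-1.0, 1.0], k_informative)
    y = intercept + z @ betas + rng.normal(0.0, noise_sd, n_compounds)
    activities = [ActivityRecord(m.id, float(v)) for m, v in zip(molecules, y)]
    # truth coefficients are on the autoscaled descriptor scale
    truth = PlantedTruth(
        informative=tuple(names),
        coefficients={n: float(b) for n, b in zip(names, betas)},
        intercept=intercept,
        noise_sd=noise_sd,
        seed=seed,
    )
    return molecules, template_map, activities, truth


def recovery_score(selected: list[str], truth: PlantedTruth) -> tuple[float, int]:
    """(recall over informative descriptors, count of false positives)."""
    informative = set(truth.informative)
    chosen = set(selected)
    recall = len(chosen & informative) / len(informative)
    false_positives = len(chosen - informative)
    return recall, false_positives
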