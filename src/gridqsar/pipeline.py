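"""End-to-end pipeline: align → fields → assemble → filter → split → train →
validate → (optional) screen, with a YAML config, provenance hashes and a
machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import chem_io, descriptor_table, screener, splitter, sw_mlr, validator
from .chem_io import TemplateMap
from .field_engine import GridSpec, ProbeSpec, build_grid
from .synthetic_data import make_field_activity_series, make_series

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters.  Only input paths and the seed have no
    defaults.  Round-trips through YAML unchanged."""

    molecules_path: str = ""
    activities_path: str = ""
    template_map_path: str = ""
    library_path: str = ""
    split_path: str = ""            # explicit split file; overrides sphere exclusion
    output_dir: str = "qsar_run"
    seed: int | None = None

    reference_id: str = ""          # default: first molecule in the file
    charge_property: str = chem_io.DEFAULT_CHARGE_PROPERTY

    grid_spacing: float = 2.0
    grid_margin: float = 4.0
    probe_rmin: float = 1.70
    probe_epsilon: float = 0.107
    probe_charge: float = 1.0
    steric_cutoff: float = 30.0
    elec_cutoff: float = 30.0
    dielectric_model: str = "constant"
    dielectric_constant: float = 1.0

    invariable_tol: float = 1e-8
    test_fraction: float = 11 / 38
    split_tol_count: int = 0

    f_enter: float = 6.0
    max_terms: int | None = None

    n_permutations: int = 100

    screen_min_activity: float = 8.0
    screen_extrapolation_bounds: tuple[float, float] = (-1.0, 1.0)

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        doc["screen_extrapolation_bounds"] = list(self.screen_extrapolation_bounds)
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text) or {}
        if "screen_extrapolation_bounds" in doc:
            doc["screen_extrapolation_bounds"] = tuple(doc["screen_extrapolation_bounds"])
        return cls(**doc)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _split_hash(split: splitter.SplitResult) -> str:
    payload = json.dumps([sorted(split.training_ids), sorted(split.test_ids)])
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_template_map(path: str | Path) -> TemplateMap:
    """Template map as YAML/JSON: ``template_atom_indices`` plus a
    ``matched_indices`` mapping of molecule id -> atom index list."""
    doc = yaml.safe_load(Path(path).read_text())
    return TemplateMap(
        template_atom_indices=[int(i) for i in doc["template_atom_indices"]],
        matched_indices={
            str(k): [int(i) for i in v] for k, v in doc.get("matched_indices", {}).items()
        },
    )


def simulate_inputs(config: RunConfig, n_compounds: int = 38) -> None:
    """Write a synthetic congeneric series + activities (+ a small library)
    into the configured input paths, so the full CLI path runs without any
    external data."""
    if config.seed is None:
        raise ValueError("config.seed is required")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    molecules, template_map, activities, _truth = make_field_activity_series(
        n_compounds, seed=config.seed,
        spacing=config.grid_spacing, margin=config.grid_margin,
    )
    config.molecules_path = str(out / "molecules.sdf")
    config.activities_path = str(out / "activities.csv")
    config.template_map_path = str(out / "template_map.yaml")
    chem_io.write_molecules(molecules, config.molecules_path)
    chem_io.write_activities(activities, config.activities_path)
    Path(config.template_map_path).write_text(
        yaml.safe_dump(
            {
                "template_atom_indices": template_map.template_atom_indices,
                "matched_indices": template_map.matched_indices,
            }
        )
    )
    library, _ = make_series(20, seed=config.seed + 1)
    lib_map = TemplateMap(
        template_atom_indices=template_map.template_atom_indices,
        matched_indices={m.id: template_map.template_atom_indices for m in library},
    )
    config.library_path = str(out / "library.sdf")
    chem_io.write_molecules(library, config.library_path)
    Path(out / "library_map.yaml").write_text(
        yaml.safe_dump(
            {
                "template_atom_indices": lib_map.template_atom_indices,
                "matched_indices": lib_map.matched_indices,
            }
        )
    )
    logger.info("simulated %d compounds + 20 library molecules under %s", n_compounds, out)


def run_full(config: RunConfig) -> dict:
    """Execute every stage and write all artifacts under ``output_dir``.
    Returns the run manifest (also written as ``manifest.json``)."""
    if config.seed is None:
        raise ValueError("config.seed is required")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    probe = ProbeSpec(
        vdw_rmin=config.probe_rmin,
        vdw_epsilon=config.probe_epsilon,
        charge=config.probe_charge,
    )

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **info}
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

        return done

    try:
        done = stage("align")
        molecules = chem_io.read_molecules(
            config.molecules_path, charge_property=config.charge_property
        )
        template_map = _read_template_map(config.template_map_path)
        reference_id = config.reference_id or molecules[0].id
        aligned, rmsds = chem_io.align_series(molecules, reference_id, template_map)
        done(n_molecules=len(aligned), max_rmsd=max(rmsds.values()))

        done = stage("fields")
        grid = build_grid(aligned, spacing=config.grid_spacing, margin=config.grid_margin)
        matrix = descriptor_table.assemble(
            aligned, grid, probe,
            dielectric_model=config.dielectric_model,
            dielectric_constant=config.dielectric_constant,
        )
        n_before = matrix.shape[1]
        matrix = descriptor_table.drop_invariable(matrix, tol=config.invariable_tol)
        matrix.to_csv(out / "descriptors.csv")
        done(grid_points=grid.n_points, descriptors_before=n_before,
             descriptors_after=matrix.shape[1], grid_hash=matrix.grid_hash)

        done = stage("split")
        activities = chem_io.read_activities(config.activities_path)
        if config.split_path:
            split = splitter.SplitResult.from_csv(config.split_path)
        else:
            split = splitter.find_radius(
                matrix, activities, config.test_fraction, tol_count=config.split_tol_count
            )
        split.to_csv(out / "split.csv")
        done(n_train=split.n_train, n_test=split.n_test, radius=split.radius)

        done = stage("train")
        act = {r.compound_id: r.pIC50 for r in activities}
        x_train = matrix.data.loc[split.training_ids]
        y_train = np.array([act[c] for c in split.training_ids])
        model = sw_mlr.fit_qsar(
            x_train, y_train,
            f_enter=config.f_enter, max_terms=config.max_terms,
            grid_hash=matrix.grid_hash, split_hash=_split_hash(split),
        )
        model = validator.recompute_external_stats(model, matrix.data, activities, split)
        model.to_json(out / "model.json")
        done(selected=model.selected, r2=model.r2, q2=model.q2, pred_r2=model.pred_r2)

        done = stage("validate")
        report = validator.y_randomization(
            matrix.data, activities, split,
            n_permutations=config.n_permutations, seed=config.seed,
            f_enter=config.f_enter, max_terms=config.max_terms,
        )
        report.to_json(out / "randomization.json")
        fitness = validator.fitness_data(model, matrix.data, activities, split)
        fitness.to_csv(out / "fitness.csv", index=False)
        done(z_scores=report.z_scores)

        if config.library_path:
            done = stage("screen")
            library = chem_io.read_molecules(
                config.library_path, charge_property=config.charge_property
            )
            lib_map_path = Path(config.library_path).with_name("library_map.yaml")
            if lib_map_path.exists():
                lib_map = _read_template_map(lib_map_path)
                by_id = {m.id: m for m in molecules}
                reference = by_id[reference_id]
                library = [
                    chem_io.align_to_template(m, reference, lib_map)[0]
                    if m.id in lib_map.matched_indices else m
                    for m in library
                ]
            lib_matrix = descriptor_table.assemble(
                library, grid, probe,
                dielectric_model=config.dielectric_model,
                dielectric_constant=config.dielectric_constant,
            )
            results = screener.screen_library(model, lib_matrix)
            screener.write_hits(results, out / "hits_all.csv")
            hits = screener.filter_hits(
                results, config.screen_min_activity, config.screen_extrapolation_bounds
            )
            screener.write_hits(hits, out / "hits_filtered.csv")
            done(n_library=len(results), n_hits=len(hits))
    except Exception as exc:
        failed = next(
            (s for s in ("align", "fields", "split", "train", "validate", "screen")
             if s not in manifest["stages"]), "unknown",
        )
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
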