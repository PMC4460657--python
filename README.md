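# gridqsar

Grid molecular-field 3D-QSAR modelling and virtual screening for congeneric
small-molecule series:

- **chem_io** — SDF/MOL input (partial charges from an SDF property or
  Gasteiger fallback, packaged vdW parameter table), pIC50 conversion, and
  rigid least-squares template alignment.
- **field_engine** — steric (Lennard-Jones) and electrostatic (Coulomb)
  probe interaction energies on a rectangular grid around the aligned series
  (default: 2 Å spacing, 4 Å margin, sp3-carbon probe with +1 charge,
  energies clamped at ±30 kcal/mol).
- **descriptor_table** — compound × descriptor matrix (`S_i`/`E_i` columns,
  x-fastest 1-based grid indexing) with invariable-column removal.
- **splitter** — sphere-exclusion training/test division in autoscaled
  descriptor space, plus radius search for a target test fraction; explicit
  split files are accepted for reproduction of a published split.
- **sw_mlr** — stepwise-forward multiple linear regression (partial
  F-to-enter), OLS with coefficient standard errors, leave-one-out q²,
  external pred_r², F statistic, and per-descriptor contribution percentages.
- **validator** — Y-randomization with full re-selection per permutation,
  Z-scores, normal-curve areas and empirical p-values; fitness-plot data.
- **screener** — library prediction ranked by activity with a signed,
  range-normalized applicability-domain (extrapolation) score.
- **synthetic_data** — seeded congeneric-series and planted-truth dataset
  generators so the entire pipeline is testable offline.
- **pipeline / cli** — orchestration with YAML config, provenance hashes
  and a JSON run manifest.

## Command line

Every stage is a subcommand of `gridqsar`; a synthetic end-to-end run:

```sh
gridqsar simulate --seed 7 --out run                # synthetic series + library
gridqsar run-all --config run/config.yaml --seed 7  # align→fields→split→train→validate→screen
```

Artifacts land in the output directory: `descriptors.csv` (+ grid sidecar),
`split.csv`, `model.json`, `randomization.json`, `fitness.csv`,
`hits_all.csv`/`hits_filtered.csv`, and `manifest.json`. Individual stages
(`fields`, `split`, `train`, `validate`, `screen`) re-run from those
artifacts. Real data goes in via `molecules_path` (SDF),
`activities_path` (CSV: `compound_id,pIC50` or `compound_id,value,unit`)
and `template_map_path` (YAML atom-index map) in the config.

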