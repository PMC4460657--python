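activities_path: /tmp/pytest-of-root/pytest-3/test_simulate_then_run_all0/cli_run/activities.csv
charge_property: PARTIAL_CHARGES
dielectric_constant: 1.0
dielectric_model: constant
elec_cutoff: 30.0
f_enter: 6.0
grid_margin: 4.0
grid_spacing: 2.0
invariable_tol: 1.0e-08
library_path: /tmp/pytest-of-root/pytest-3/test_simulate_then_run_all0/cli_run/library.sdf
max_terms: null
molecules_path: /tmp/pytest-of-root/pytest-3/test_simulate_then_run_all0/cli_run/molecules.sdf
n_permutations: 5
output_dir: qsar_run
probe_charge: 1.0
probe_epsilon: 0.107
probe_rmin: 1.7
reference_id: ''
screen_extrapolation_bounds:
- -1.0
- 1.0
screen_min_activity: 8.0
seed: 5
split_path: ''
split_tol_count: 0
steric_cutoff: 30.0
template_map_path: /tmp/pytest-of-root/pytest-3/test_simulate_then_run_all0/cli_run/template_map.yaml
test_fraction: 0.2894736842105263
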