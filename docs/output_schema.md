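# Output schema

`ecocavity.interface.write_results` writes, for an output stem `out`:

* `out.csv` — the results table, one row per realization or grid point,
  floats formatted round-trip exactly (`%.17g`); read back losslessly
  with `ecocavity.interface.read_results`;
* `out.meta.json` — package version, UTC timestamp, row count, column
  list, any caller metadata (summary statistics, seeds, tolerances) and
  the fully expanded run configuration;
* `out.manifest.json` — SHA-256 checksums of the two files above.

## Column names

Ensemble simulation tables (`ecocavity simulate`, `run_ensemble`):

| column | meaning |
| --- | --- |
| `realization` | realization index k (seeded with `base_seed + k`) |
| `seed` | the per-realization seed actually used |
| `phi_N`, `phi_R` | surviving fraction of species / resources |
| `mean_N`, `mean_R` | first moment over **all** S (M) slots, zeros included |
| `q_N`, `q_R` | second moment over all slots |

Cavity solution tables (`ecocavity cavity` / `scan`): `sigma`, `phi_N`,
`mean_N`, `q_N`, `nu`, `delta`, `residual_norm`, `converged`,
`rs_valid`, and for consumer-resource solutions additionally `phi_R`,
`mean_R`, `q_R`, `chi`.

Phase-scan / breakdown tables (`ecocavity phase-scan`,
`scripts/acceptance.py` diagnostics): `sigma`, `sim_phi_N`, `phi_se`,
`cavity_phi_N`, `phi_dev_se` (deviation in SE units; infinite where the
cavity has no replica-symmetric root), `median_min_eig` (ensemble median
of the minimum eigenvalue of the surviving-species interaction matrix),
`n_ok` (converged realizations).
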