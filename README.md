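# lcscea

Cost-effectiveness model for annual low-dose-CT lung cancer screening versus
no screening, from a healthcare-payer perspective.

A screening decision tree (eligibility, participation, 17 annual rounds,
detection-pathway assignment, missed individuals) feeds a stage-stratified
Markov cohort model (pre-progression / post-progression / dead, three-month
cycles) with parametric survival extrapolation from summary anchors,
background mortality from a life table, full cost and utility accounting with
discounting, and one-way / probabilistic / scenario sensitivity analysis.
All appendix-style inputs (screen performance, life table, population
utilities) are generated by a calibratable synthetic-data module, so every
stage runs offline.

## Layout

| module | contents |
| --- | --- |
| `lcscea.parameters` | typed parameter tree (pydantic), YAML config I/O, base-case fixture, scenario overrides, validation |
| `lcscea.synthetic_data` | screening-outcome model + calibration, Gompertz–Makeham life table, population utilities, noisy survival anchors |
| `lcscea.survival` | parametric curve fitting (log-cumulative-hazard least squares, AIC auto-selection), per-cycle transition matrices with additive background mortality |
| `lcscea.cohort_tree` | decision tree, eligibility arithmetic, diagnosis ledger (mass-conserving across arms) |
| `lcscea.markov_engine` | deterministic cohort engine, vectorized batch path, microsimulation oracle |
| `lcscea.economics` | discounting, cost/QALY streams, arm-level and incremental results (ICER, NMB) |
| `lcscea.sensitivity` | tornado (±20%), PSA (beta/gamma/dirichlet), CEAC, scenario runner |
| `lcscea.cli_reporting` | `lcscea` CLI, results-table CSV writers, run manifests |

## CLI

```sh
lcscea base --out-dir out                 # deterministic base case
lcscea osa  --out-dir out                 # tornado CSV (±20% per parameter)
lcscea psa  --n-draws 1000 --seed 1 --out-dir out   # CE-plane scatter
lcscea ceac --n-draws 1000 --seed 1 --wtp-grid 0:150000:5000 --out-dir out
lcscea scenarios --out-dir out            # shipped scenario set
```

All commands accept `--config path.yaml`; without it the shipped base case
(`lcscea/data/table1_austria_2022.yaml`) is used. `base` writes a results
table (`table2.csv`), a versioned JSON result, a tidy diagnosis ledger and a
run manifest with the config hash.

## Library use

```python
from lcscea import table1_fixture, run_model

result = run_model(table1_fixture())
print(result.icer_qaly, result.nmb)
```

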