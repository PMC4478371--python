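# ceamodel

A cohort cost-effectiveness analysis toolkit for oncology treatment
comparisons: a monthly-cycle, three-state (stable disease / progression /
death) partitioned-survival model with constant-hazard (DEALE-style)
extrapolation beyond observed follow-up, lifetime cost and QALY
accumulation, an ICER dominance frontier, one-way deterministic
sensitivity analysis, Monte-Carlo probabilistic sensitivity analysis and
cost-effectiveness acceptability curves.

The package ships a bundled base-case scenario
(`src/ceamodel/data/table1_melanoma.yaml`) with the published economic
inputs of a three-strategy metastatic-melanoma comparison (dacarbazine,
dabrafenib, vemurafenib): monthly drug costs, adverse-event probabilities
and management costs, and drug-specific health-state utilities, all in
2013 USD. The survival curves in the fixture are **illustrative
exponential stand-ins** calibrated by median survival — the underlying
trial Kaplan-Meier curves were never published in tabulated form. Supply
digitized curves as CSV (`month,survival`) to compute trial-based totals.

## Library use

```python
import ceamodel as cm

scenario = cm.load_scenario(cm.bundled_scenario_path())   # or your own YAML/JSON
results = cm.run_scenario(scenario)                       # per-strategy cost/QALY totals
frontier = cm.build_frontier(results)                     # dominance + ICERs
samples, ceac = cm.run_psa(scenario, n_iterations=10_000, seed=42)
cm.ceac_report(ceac, wtp=100_000.0)                       # proportions optimal at a threshold
```

`make_melanoma_like_scenario(seed)` builds a fully synthetic but runnable
scenario (bundled economics + generated curves) for demos and testing.

## Command line

```sh
cea run  scenario.yaml --out out/                 # totals, frontier, per-cycle traces
cea psa  scenario.yaml --n 10000 --seed 7 --out out/   # PSA + ceac.csv
cea dsa  scenario.yaml --param dabrafenib.monthly_drug_cost \
         --low 3000 --high 9000 --steps 25 --out out/  # one-way sweep + WTP crossing
cea ceac scenario.yaml --wtp 100000 --out out/    # proportions at one threshold
```

Every command writes a `manifest.json` (scenario hash, version, seeds,
settings) sufficient to re-run bit-identically. The scenario file format
and CSV layouts are documented in `docs/scenario_schema.md`.

## Conventions

- State occupancy is partitioned directly from the curves: stable = PFS,
  progressed = OS − PFS, dead = 1 − OS.
- Costs/QALYs accrue for cycles 0..T−1 at start-of-cycle occupancy; no
  discounting and no half-cycle correction by default (both available).
- Net monetary benefit is the standard `wtp × QALY − cost`.
- PSA fits beta/gamma distributions by method of moments with
  `sd = (high − low)/3.92`; uninformative 0–1 utility ranges use an
  effective-sample-size beta centred on the base value (ν = 20,
  configurable). One master seed; per-parameter substreams are derived
  from the parameter path, so declaration order never changes results.
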