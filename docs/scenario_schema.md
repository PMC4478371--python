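# Scenario file schema (version 1)

A scenario is a YAML or JSON mapping. Unknown keys are rejected at every
level; all validation errors name the dotted path of the offending field.

## Top level

| key | type | default | meaning |
|---|---|---|---|
| `schema_version` | int | required | must equal `1` |
| `strategies` | list | required | one entry per treatment arm |
| `survival` | mapping | required | strategy name → `{os, pfs}` curves |
| `wtp_default` | number > 0 | `100000` | willingness-to-pay threshold, USD/QALY |
| `cycle_length_months` | int ≥ 1 | `1` | model cycle length |
| `max_cycles` | int ≥ 1 | `600` | lifetime horizon cap (cycles) |
| `discount_rate_annual` | number ≥ 0 | `0` | annual discount rate |
| `settings` | mapping | see below | model conventions |

### `settings`

| key | type | default | meaning |
|---|---|---|---|
| `anchor_month` | int ≥ 1 | `8` | month at which the extrapolation hazard is estimated |
| `half_cycle` | bool | `false` | trapezoidal within-cycle accrual |
| `ae_cost_basis` | `alive` \| `stable_only` | `alive` | occupancy carrying AE management costs |

## Distributions

Anywhere a parameter value is expected, either a bare number (treated as
fixed) or a mapping:

```yaml
{base: 988.86, low: 678.29, high: 1356.85, family: gamma}
```

`low ≤ base ≤ high` always. `family` is one of `beta` (range within
[0, 1]), `gamma` (`low ≥ 0`) or `fixed` (excluded from probabilistic
sampling). Omitted `low`/`high` default to `base`.

## `strategies[*]`

| key | type | meaning |
|---|---|---|
| `name` | string | unique strategy name |
| `monthly_drug_cost` | distribution | USD per month alive |
| `utility_stable` | distribution | stable-disease utility in [0, 1] |
| `utility_progression` | distribution | progression utility in [0, 1] |
| `crossover_monthly_cost` | number ≥ 0 | USD per unit of progression-state occupancy per cycle (comparator-arm crossover onto the experimental drug); default 0 |
| `adverse_events` | list | see below; default empty |

### `adverse_events[*]`

| key | type | meaning |
|---|---|---|
| `name` | string | event name |
| `grade_band` | `g12` \| `g34` | severity band |
| `monthly_probability` | distribution | probability per cycle on drug, in [0, 1] |
| `management_cost` | distribution | USD per month on treatment |
| `ae_state_utility` | number in [0, 1] or null | optional dedicated AE-state utility |

## `survival.<strategy>.{os,pfs}`

One of three forms:

```yaml
# inline
os: {months: [0, 1, 2], survival: [1.0, 0.9, 0.8], anchor_month: 2}
# external CSV with columns month,survival (path relative to the scenario file)
os: {csv: curves/os_armA.csv, anchor_month: 8}
# exponential shorthand calibrated by median survival
os: {exponential: {median_months: 9.0, follow_up_months: 8}}
```

Curves must start at month 0 with `S(0) = 1`, use a unit month grid, and be
nonincreasing. `anchor_month` defaults to `settings.anchor_month`.

## Results CSV layouts

* totals: `name,total_cost,total_qaly`, rows sorted by total cost ascending;
* frontier: `name,total_cost,total_qaly,inc_cost,inc_qaly,icer,status`
  (status ∈ `frontier`, `dominated`, `extended_dominated`), same ordering;
* CEAC: `wtp` column then one proportion column per strategy.

All files are UTF-8 with `.` decimal separator; costs carry 2 decimals,
QALYs and proportions 4.

## Net monetary benefit convention

NMB is computed in the standard form `wtp × QALY − cost`. (The source
publication prints `λ × (Effect − Cost)`, which is dimensionally
inconsistent; the standard form is what an acceptability curve requires.)
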