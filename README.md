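# airburden

State-level analysis of air-pollution-attributable disease burden and its
economic cost. The package implements:

- **`airburden.synthetic_data`** — seeded generation of synthetic state panels
  (population by 5-year age group 0–95+, abridged life tables expanded to
  single years, age-specific employment, economy parameters, exposure
  summaries, all-risk cause envelopes for eight causes) and attributable
  burden built by applying known PAFs, so the analysis stages are fully
  testable without any external download.
- **`airburden.burden`** — comparative-risk-assessment arithmetic: piecewise
  linear relative-risk curves with a TMREL, continuous and categorical
  population attributable fractions, attributable deaths/YLL/YLD/DALY, crude
  and age-standardised rates, percent changes, Pearson correlation.
- **`airburden.econ`** — output-based cost of illness: output per worker
  (labour share × GDP / employed), expected per-person output with a 30%
  non-market share for people not working, life-table survival weighting, 6%
  discounting of lost output over the remainder of working life (horizon age
  65, both configurable), mortality and morbidity losses per state × risk,
  and a 4–8% discount-rate sensitivity analysis.
- **`airburden.report`** — national aggregation with recomputed %-of-GDP and
  per-capita figures, shares/ratios/cause decomposition, simplified
  draw-based uncertainty intervals, and arithmetic consistency checks of the
  published national summary at printed precision.
- **`airburden.io_cli`** — CSV schemas with round-trip readers/writers,
  YAML run configuration validated by pydantic, and the `airburden` CLI.

## CLI

```sh
airburden --seed 1 --out-dir output simulate          # panels + risk curves
airburden --out-dir output burden                     # attributable burden
airburden --out-dir output econ                       # losses + sensitivity
airburden --out-dir output report                     # national summary + UIs
airburden --out-dir output verify                     # arithmetic checks
airburden simulate --print-config                     # full default config
```

Stages read each other's outputs from `--out-dir` (overridable per stage) and
log a machine-parsable `STAGE=... SEED=... ROWS=... SECONDS=...` line to
stderr. `verify` exits nonzero iff any published-summary arithmetic check
fails; schema or invariant violations in any stage name the offending file,
column, state and field.

## Modelling conventions

- The death year (t = 0) counts as one lost, undiscounted year; growth in
  output per worker applies from t = 1.
- Deaths within a 5-year age group are assigned the group midpoint age
  (e.g. 62 for 60–64); deaths in the open 95+ group carry zero PV under the
  default horizon.
- Deaths below the minimum working age (15) contribute the discounted value
  of the future working life from age 15.
- Morbidity is valued as a single undiscounted year of expected output per
  YLD at the age it occurs; it is therefore invariant to the discount rate
  and the life table.
- Monetary quantities are carried in US$ millions at full double precision;
  half-up rounding happens only at the reporting layer.
- Component-risk PAFs are never renormalised; parent-aggregate burden uses a
  multiplicative (independence) combination and may be less than the
  component sum.
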