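# jellyom

Analysis pipeline for degradation experiments on gelatinous detrital
organic matter (jelly-OM): leaching-rate normalization and stoichiometry,
batch-culture growth kinetics with the bacterial carbon budget
(BCD / BP / BR / BGE), amino-acid and nutrient pool bookkeeping,
PSMs-per-residue proteome turnover, and reads-per-million community
abundance — driven either by tidy measurement tables or by a synthetic
batch-culture generator with known ground truth.

## Layout

| module | what it does |
| --- | --- |
| `jellyom.stoichiometry` | μmol↔μg conversions, molar C:N, cell→carbon, pool consumption % |
| `jellyom.leaching` | per-mg-dry-mass release rates, TOC/DIN partitioning, bloom-decay enrichment predictions |
| `jellyom.growth` | exponential-window detection, μ, per-flask carbon budgets, pooled t-tests, replicate aggregation |
| `jellyom.pools` | TDHAA/DFAA/DCAA bookkeeping, mol%, phase-wise net rates |
| `jellyom.proteome` | PSMs/AA abundance proxy, pool totals, turnover and annotation rollups |
| `jellyom.abundance` | RPM normalization, MAG relative abundance, FISH population fold changes |
| `jellyom.simulate` | synthetic leaching / batch-culture / PSM / read-count generators |
| `jellyom.pipeline` | end-to-end orchestration, run config, worked-example report |
| `jellyom.records` | tidy CSV schema (`experiment, replicate, treatment, time_h, analyte, value, unit`) |

## CLI

```bash
jellyom simulate --seed 1 --outdir sim_out          # synthetic inputs + ground truth
jellyom leach sim_out/leaching_series.csv -o rates.csv
jellyom budget sim_out/batch_series.csv -o budget_out
jellyom pools sim_out/batch_series.csv -o net_rates.csv
jellyom proteome sim_out/psm_table.tsv -o turnover.csv
jellyom abundance sim_out/read_counts.tsv -o abundance.csv
jellyom report config.yaml                          # full simulate→analyze→report run
jellyom worked-example                              # published desk arithmetic, pass/fail
```

A `report` config is YAML with keys matching `jellyom.pipeline.RunConfig`
(`seed`, `outdir`, `method: ols|endpoint`, `sim: {...}` overrides for
`SimParams`, optional `inputs: {batch_csv, leaching_csv}` to analyze real
data instead of simulating). Unknown keys are rejected.

## Conventions

- Rates are signed: negative = net consumption, positive = net
  accumulation; nothing is clamped, suspicious values carry flags.
- Budgets satisfy BR + BP = BCD exactly; BGE is averaged across
  replicate-level ratios (the ratio-of-means alternative is reported as a
  diagnostic only).
- Slope estimation defaults to OLS over the window; endpoint differences
  are available everywhere via `method="endpoint"`.
- Full precision is kept internally; rounding (2 significant figures for
  rates, 1 decimal for ratios) happens only at display time.

## Tests

```bash
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria: published desk
arithmetic (amendment pulses, C:N ratios, pool sums, proteome turnover,
bloom loads) plus structural invariants and 100-seed stochastic
parameter-recovery checks on the synthetic generators.

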