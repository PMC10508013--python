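# finprot

Financial risk protection indicators for household health-expenditure
surveys: catastrophic health expenditure (CHE) and medical impoverishment
(MI) classification under the standard threshold definitions,
survey-weighted incidence estimation with confidence intervals, urban–rural
and income-quartile inequality gaps with chi-square tests, multi-wave trend
series, and a weighted probit determinants model with average marginal
effects. A synthetic household-survey generator with a fully known
data-generating process makes every pipeline stage testable end to end
without any restricted microdata.

## Indicator definitions

CHE (out-of-pocket health spending at or above a threshold share of a
denominator, comparator `>=`):

| label            | denominator                          | threshold |
|------------------|--------------------------------------|-----------|
| `che_nonfood_40` | nonfood capacity (consumption − food)| 40%       |
| `che_total_10`   | total consumption                    | 10%       |
| `che_total_25`   | total consumption                    | 25%       |

MI (household above the poverty line on gross per-capita consumption but
strictly below it net of out-of-pocket health spending; comparator `<`):

| label           | poverty line                                             |
|-----------------|----------------------------------------------------------|
| `mi_abs_1.9usd` | 1.9 USD/person-day × PPP 3.52 × CPI 1.13 = 7.56/day      |
| `mi_abs_3.1usd` | 3.1 USD/person-day × PPP 3.52 × CPI 1.13 = 12.33/day     |
| `mi_relative`   | 60% of the weighted median per-capita consumption        |

Edge rules: nonpositive capacity to pay ⇒ CHE iff OOP > 0; zero OOP is never
CHE and never MI; being exactly on a poverty line is not poor; the weighted
MI incidence equals the net-minus-gross poverty headcount difference exactly.

## CLI

```sh
# generate a synthetic survey (canonical CSV schema)
finprot simulate --n 20000 --seed 7 --out households.csv

# classify under the canonical six definitions
finprot flags --input households.csv --out flags.csv

# weighted incidence with 95% CIs; subgroup gaps; trends; probit AMEs
finprot incidence --flags flags.csv
finprot gaps --flags flags.csv --grouping urban
finprot trend --flags flags.csv --indicator che_nonfood_40
finprot probit --input households.csv --outcome che_nonfood_40

# full pipeline from a YAML config (see configs/run_synthetic.yaml)
finprot run --config configs/run_synthetic.yaml --out-dir out
```

The pipeline writes `incidence.csv/.txt`, `gaps.csv/.txt`, `trend.csv`
(multi-wave runs), `regression.csv/.txt`, the harmonized `households.csv`
and `flags.csv`, validation/load reports, and a `manifest.json` with the
config hash, seed, and reconciled row counts. Identical configs reproduce
byte-identical outputs.

Real survey files are read through per-survey *dialect* configs
(`configs/dialects/*.yaml`) that map source column names onto the canonical
schema, mark monthly-reported fields for ×12 annualization, and document
concept differences between surveys. Monetary fields can be rebased to a
common price year with a CPI series (`configs/cpi.yaml`).

## Layout

- `src/finprot/io.py` — dialect-mapped loading, validation, CPI rebasing
- `src/finprot/indicators.py` — CHE/MI classification, poverty lines
- `src/finprot/estimation.py` — weighted incidence, quartiles, gaps, trends
- `src/finprot/regression.py` — weighted probit, robust SEs, marginal effects
- `src/finprot/synthetic.py` — generator with known ground-truth incidences
- `src/finprot/pipeline.py`, `cli.py` — end-to-end orchestration and CLI
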