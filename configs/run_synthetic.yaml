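# End-to-end pipeline run on the bundled synthetic generator.
# `finprot run --config configs/run_synthetic.yaml --out-dir out`
synthetic:
  n_households: 20000
  n_provinces: 25
seed: 7
# Omitted sections fall back to the canonical definition set:
# CHE at 40% nonfood capacity, 10% and 25% of total consumption;
# MI at the 1.9 and 3.1 USD/day absolute lines (PPP 3.52, CPI 1.13, 365 days)
# and the 60%-of-weighted-median relative line.
groupings:
  - residence
  - income_quartile
regression_outcomes:
  - che_nonfood_40
  - mi_abs_1.9usd
output_dir: finprot_out
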