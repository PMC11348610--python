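# Swiss university-hospital base case: computer-vision vs fully manual
# skin prick tests. Probabilities as positive counts r of sample n;
# costs in CHF per test at 2023 prices (further_tests is dimensionless).
proportions:
  - {label: prevalence, r: 1061, n: 8357, dsa_low: 0.10, dsa_high: 0.20}
  - {label: manual_sensitivity, r: 1485, n: 2289, dsa_low: 0.64, dsa_high: 0.66}
  - {label: manual_specificity, r: 9366, n: 9627, dsa_low: 0.97, dsa_high: 0.98}
  - {label: dspt_sensitivity, r: 1448, n: 2289, dsa_low: 0.62, dsa_high: 0.64}
  - {label: dspt_specificity, r: 9132, n: 9627, dsa_low: 0.94, dsa_high: 0.96}
costs:
  - {label: manual_cost, mean: 39.37, dsa_low: 31.5, dsa_high: 47.2}
  - {label: dspt_cost, mean: 30.70, dsa_low: 24.6, dsa_high: 36.9}
  - {label: further_tests, mean: 2.0, sd: 0.4, dsa_low: 1.6, dsa_high: 2.4}
device:
  capital: 10400
  life_years: 10
  annual_service: 1040
  tests_per_year: 5200
settings:
  retest_strategy: manual_retest
  n_simulations: 10000
  seed: 0
  n_patients: 100000
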