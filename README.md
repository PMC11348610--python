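# sptcca

Early cost-consequence model comparing **computer-vision-based skin prick
tests (SPTs)** with **standard fully manual SPTs** from a Swiss
university-hospital perspective.

Skin prick tests are the usual first-line check for suspected allergy: a
wheal at least 3 mm larger than the negative control indicates
sensitization. A computer-vision reader shortens the read-and-record step
(3 min vs 5.5 min per test) at a small capital cost, but is slightly less
accurate than a manual read. This package quantifies the net cost
consequence per tested patient for an allergology department, for health
economists and hospital analysts evaluating (semi)automated diagnostics.

## The model

A decision tree chooses between two strategies; within each, a referred
patient is truly sensitized with probability *p* (prevalence) and the test
result follows the arm's sensitivity *Se* or specificity *Sp*, giving four
terminal pathways per arm with probabilities

```
P(TP) = p·Se      P(FN) = p·(1−Se)
P(FP) = (1−p)·(1−Sp)   P(TN) = (1−p)·Sp
```

Every pathway costs one test (C_manual = CHF 39.37, C_cv = CHF 30.70,
including CHF 0.40/test device amortization). A false negative leads to a
second referral and is surcharged (F − 1) retests, F = 2 further tests on
average, priced at the manual per-test cost by default. A false positive
has no direct hospital cost. The expected cost per strategy is the
probability-weighted sum of pathway payoffs:

```
E[C_arm] = C_arm + p·(1−Se_arm)·(F−1)·C_retest
```

and the incremental cost is `E[C_cv] − E[C_manual]` (negative favours the
computer-vision arm). Around this deterministic tree sit a one-way tornado
analysis over each parameter's plausible range, a Beta/Gamma Monte Carlo
probabilistic sensitivity analysis (probabilities ~ Beta(r, n−r), costs ~
method-of-moments Gamma), and a patient-level microsimulation used as an
independent oracle for the rollback.

## Worked example

```bash
$ sptcca basecase
                   strategy  expected_cost_chf_per_test
                     manual                   41.125661
                       dspt                   32.536456
incremental (dspt - manual)                   -8.589205
savings (manual - computer-vision): CHF 8.59 per test
```

The manual strategy costs CHF 41.13 per tested patient in expectation
(CHF 39.37 per test plus the false-negative retest burden), the
computer-vision strategy CHF 32.54, so reading SPTs with the
computer-vision device saves **CHF 8.59 per test** at the base-case point
estimates. The full bundle —

```bash
$ sptcca report --seed 1 --out results/
```

— additionally writes the parameter table, the tornado CSV/plot (all eight
one-way excursions keep the incremental cost negative; the two arm-cost
parameters dominate), the 10,000-draw PSA (`prob_cost_saving` ≈ 0.81, PSA
mean ≈ −8.58, matching the deterministic value), a microsimulation
cross-check and a manifest of every input used. `sptcca psa`,
`sptcca dsa`, `sptcca microsim` and `sptcca validate` run single stages;
`--config` points at a YAML model specification (see
`src/sptcca/data/base_case.yaml`), `--strategy same_arm_retest` switches
the false-negative retest to the arm's own cost.

Library use mirrors the CLI:

```python
from sptcca import base_case_inputs, expected_incremental, run_psa

res = expected_incremental(base_case_inputs())
print(res.ev_manual, res.ev_dspt, res.savings)  # 41.13  32.54  8.59
psa = run_psa(base_case_inputs(), n_simulations=10_000, seed=1)
print(psa.prob_cost_saving)
```

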