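# Methods

## Model and assumptions

The package implements an early cost-consequence model: a two-strategy
decision tree over a single diagnostic episode, evaluated from the
hospital (allergology department) perspective in 2023 Swiss francs over a
one-year horizon. No discounting is applied and no health outcomes are
valued — the comparison is purely between expected costs per tested
patient, which is why there is no ICER, QALY or acceptability-curve
machinery anywhere in the package.

Each referred patient is sensitized with probability `prevalence`; the
test outcome is conditionally Bernoulli with the arm's sensitivity (if
sensitized) or specificity (if not). Four mutually exclusive pathways per
arm (TP, FN, FP, TN) follow. Payoffs:

- every pathway carries the arm's per-test cost;
- a **false negative** is assumed to trigger a second referral and repeat
  testing, surcharged `(further_tests − 1) × retest cost`;
- a **false positive** carries no further hospital cost (SPTs are not a
  standalone diagnosis, so a false positive is resolved against clinical
  history rather than repeat testing);
- true results end the episode.

The strategy's expected cost is the probability-weighted pathway sum
(expected-value rollback); the incremental cost is
`EV(computer-vision) − EV(manual)`, negative when the computer-vision arm
saves money. Both sign conventions appear explicitly in exports.

### Retest costing

`retest_strategy` decides how the false-negative repeat test is priced:

- `manual_retest` (default): the repeat test is a manual SPT in both arms.
  This is the only reading under which higher sensitization prevalence
  erodes the computer-vision saving (the documented direction of the
  prevalence effect): the less sensitive computer-vision arm generates
  more false negatives, each costing a full manual retest.
- `same_arm_retest`: the repeat test uses the arm's own technique. Under
  this reading the cheaper arm also retests cheaply and the prevalence
  effect reverses; it is kept as a configurable alternative and is the
  natural convention for the arm-swap antisymmetry property.

With `further_tests = 2` the surcharge is exactly one retest, i.e. a
"repetition of SPT-related costs". The multiplier is continuous (it is
Gamma-distributed in the PSA, Gamma(25, 0.08)); draws below 1 are
astronomically rare but would flip the surcharge into a rebate, so the
sampler emits a warning rather than truncating.

## Parameters

Probability parameters are defined by counts `r` of `n` (point estimate
`r/n`) and sampled as Beta(r, n − r), whose mean is exactly `r/n`. Note
the distribution is parameterized by the counts themselves, not by a
fitted variance. Cost parameters are defined by mean and SD and sampled
as method-of-moments Gamma (shape = (mean/sd)², scale = sd²/mean). An
omitted SD defaults to 20% of the mean, the same rule that generates the
±20% deterministic ranges.

Base case (bundled as `data/base_case.yaml`):

| parameter | value | one-way range |
|---|---|---|
| prevalence (grass-pollen sensitization, referred adults) | 1061/8357 = 0.127 | 0.10–0.20 |
| manual sensitivity / specificity | 1485/2289 = 0.649, 9366/9627 = 0.973 | 0.64–0.66, 0.97–0.98 |
| computer-vision sensitivity / specificity (2.5 pts lower) | 1448/2289 = 0.633, 9132/9627 = 0.949 | 0.62–0.64, 0.94–0.96 |
| manual cost, CHF/test | 39.37 = 19.41 materials + 19.96 staff | 31.5–47.2 |
| computer-vision cost, CHF/test | 30.70 = 19.41 + 10.89 + 0.40 device | 24.6–36.9 |
| further tests (total for an FN patient) | 2.0 (SD 0.4) | 1.6–2.4 |

Staff cost is minutes × rate rounded to the centime. The canonical rate,
19.96/5.5 ≈ CHF 3.629/min, is back-derived from the per-test staff costs
so that both arms' printed components reproduce exactly; a naive
salary-per-contract-minute calculation gives a much lower rate and is not
internally consistent with the per-test totals, so the per-test figures
are treated as authoritative (they plausibly embed employer overheads).
The device contributes CHF 0.40/test: straight-line depreciation of a
CHF 10,400 reader over 10 years plus CHF 1,040/year service, spread over
5,200 tests/year. Specificities do not enter the expected cost (TP, FP
and TN pathways all cost one test), so their tornado bars have zero
width; they are still varied and exported for completeness.

At these point estimates the rollback gives EV(manual) = 41.13,
EV(computer-vision) = 32.54, a saving of CHF 8.59 per test. The published
headline figure for this comparison is ≈ CHF 7; no tree reading we could
construct (same-arm retest, manual retest, surcharge variants) reproduces
exactly 7 — closed-form values fall between 8.5 and 9.0 — so the package
treats 7 as a lower bound the reconstruction comfortably clears rather
than a value to match.

## Sensitivity analyses

**One-way (tornado).** Each of the eight parameters is set to its range
bounds, all others at base; entries are ranked by
`|incremental(high) − incremental(low)|`, ties broken alphabetically.
Each parameter enters the model in exactly one place, so varying the
manual cost also moves the retest surcharge it prices. Bounds are
evaluated exactly; no interior sampling.

**Probabilistic (PSA).** All eight parameters are drawn independently
(no correlation structure is assumed — a simplification; accuracy
parameters estimated from the same study would in reality co-vary) in a
fixed order (prevalence, manual Se, manual Sp, computer-vision Se,
computer-vision Sp, manual cost, computer-vision cost, further tests)
from one seeded `numpy` generator, so a seed fully determines the run.
Each draw is plugged into the deterministic tree. Because the incremental
cost is multilinear in independently drawn parameters, its Monte Carlo
mean converges to the deterministic plug-in value — a property the tests
exploit. Default 10,000 draws (~1 s).

**Convergence.** The running mean is checkpointed every `block` draws
(default 500); the run is declared stable at the first checkpoint whose
running mean differs from the previous checkpoint's by strictly less than
`tolerance` (default 1%, relative). The strict inequality means an
exactly-zero trace (e.g. symmetric ±c draws with an even block) never
"stabilises", which is the conservative choice for degenerate inputs.

## Microsimulation oracle

`simulate_cohort` pushes individual patients through the same pathway
logic with per-patient Bernoulli draws and per-patient cost accrual. It
exists to validate the rollback, not to extend it: by construction the
per-arm cost distribution has at most two support points (base cost, base
plus surcharge), and the cohort mean converges to the analytic EV at rate
SE = sd/√n. Tests check agreement within 3 SE for the base case (10⁶
patients), for 100 generator scenarios (10⁵ patients each), and exactly
for degenerate corners (prevalence or sensitivity 0/1, further_tests 1).
Arms are simulated with independent randomness by default, mirroring a
between-population comparison; `paired=True` shares the sensitization
draw across arms for variance-reduced contrasts.

`random_scenario` generates valid parameter sets with the statistical
structure the model assumes — proportions with binomial provenance
(1 ≤ r ≤ n−1, n between 50 and 10,000), right-skewed log-normal costs
around tens of CHF, a further-tests multiplier in [1, ~4], and a random
retest strategy — for property-based testing.

## What the synthetic cohort does and does not emulate

The generator realizes exactly the model's assumptions: homogeneous
patients, conditionally independent single test per episode, one
two-valued cost per arm. It does **not** emulate real-world features the
model itself omits — patient covariates, within-patient correlation of
repeat tests, a retest that can itself be falsely negative (the surcharge
is charged once, matching the tree), GP/societal costs, or health
outcomes. Passing oracle tests therefore demonstrates that the rollback
and the simulator implement the same model, not that the model captures
the clinic.

## Numerical choices

- Chance-node probabilities must sum to 1 within 1e−9; payoffs are kept
  as exact binary doubles of the printed inputs with no intermediate
  rounding (money is rounded to 2 decimals only for display).
- Beta sampling degenerates gracefully: r = 0 or r = n yields the
  constant 0 or 1 rather than an invalid Beta.
- Monetary outputs are CHF throughout (CHF 1 = €1 fixed where the device
  price originated in euros); probabilities are reported to 6 decimals.
- The classification goodness-of-fit check uses a chi-square test at
  α = 0.001, strict enough to catch misspecification (swapped
  sensitivity/specificity fails immediately at n = 10⁵) while keeping
  seeded property tests stable; a nonzero count in a zero-probability
  class is a hard error, not a test statistic.
- Test problem sizes (10⁶-patient base-case cohort, 10⁵-patient scenario
  sweeps, 10,000-draw PSA) were chosen so the full suite runs in well
  under a minute while keeping Monte Carlo standard errors far below the
  effects being checked.

## Known limitations

- Parameter independence in the PSA overstates how freely accuracy and
  prevalence can co-move.
- The prevalence inputs date from a 1995 national survey; the ±range
  (0.10–0.20), not the point estimate, carries the contemporary value.
- The model is two-arm, one-episode, hospital-perspective only; extending
  to Markov states, QALYs or societal costs is explicitly out of scope.
- The cost "shift invariance" of the probability of cost saving holds
  exactly only without the false-negative surcharge (further_tests = 1);
  with the surcharge, a common shift in both arm costs moves the
  incremental by `shift × prevalence × (Se_manual − Se_cv)`.
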