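# Methods

## Structural model

One virtual subject is described by a five-state mass-balance system (plus
two auxiliary integrals): the 1-month product's fast (zero-order) and slow
(first-order) depots, the 3-month product's rapid and slow saturable
depots, and a central compartment with linear elimination `CL/V *
Qcentral`.  Every injection of a given product replenishes that product's
depots at a single site, so amounts accumulate across injections.

Bookkeeping of the zero-order phase: at injection time the whole dose
enters the fast depot state; a constant rate `f1 * Dose / tl1` drains it
for `tl1` days, at which point the fast portion `f1 * Dose` has left
exactly and the remaining `(1 - f1) * Dose` transfers to the first-order
depot.  Keeping the pending remainder inside the fast-depot state (rather
than appearing from nowhere at the window end) is what makes the mass
balance an exact invariant at every output time: the sum of all amounts
plus cumulative elimination equals administered-to-date plus the initial
body burden `Qc0`, to machine precision for the fixed-step solver and to
integration tolerance for the adaptive one.  Overlapping zero-order
windows from successive injections add their rates.

Units: time in days, amounts in mg eq. of paliperidone (doses used as-is,
no molecular-weight conversion), volumes in litres; concentrations in
ng/mL (`Q/V * 1000`).  Partial AUC is carried as an extra ODE state in
ng/mL·day, so AUC over an interval is a difference of state values rather
than a quadrature of sampled outputs.

## Solvers

Two interchangeable integration routes:

* `solver="lsoda"`: adaptive LSODA at rtol 1e-8 / atol 1e-10, integrating
  segment-by-segment with hard stops at every dosing and window-switch
  event.  This is the reference route.
* `solver="rk4"` (default): an event-aligned fixed-step RK4 kernel
  compiled with numba that integrates an arbitrary batch of subjects in
  one call.  Nodes include all events and requested outputs, refined to a
  step bound (0.5 day for trial simulation, 1 day for exposure batches,
  3 days inside the MCMC likelihood).  Within each node interval the step
  is subdivided so that `h * lambda < 0.8`, where `lambda` bounds the
  fastest local eigenvalue (elimination `CL/V`, PP1M release `ka1`, and
  the near-empty slopes `kar3_max/kar3_50` and `gamma*kas3_max/kas3_50`
  of the saturable release laws); this keeps RK4 inside its stability
  region even for the extreme parameter proposals an MCMC run explores.

The two routes agree to ~1e-5 relative on whole-study profiles (asserted
in tests); population-scale workloads (10^4–10^6 subject solves for
power, type-I and safe-space maps) are only practical on the vectorised
route.  States within `-1e-9` of zero are clamped to zero; more negative
states raise; non-finite states raise in direct simulation and become
`-inf` log-likelihood inside the sampler.

Model-integrated exposure uses the peak of a 100-point uniform grid over
the analysis interval (within 0.5% of a 10,000-point refinement at steady
state) and the AUC state difference.

## Population model and formulation shift

`ka1, kar3_50, kas3_max, kas3_50, CL, V` are lognormal across subjects
with zero random-effect covariances (only variances are used);
`kar3_max` and `gamma` are shared by all subjects; `Qc0` is lognormal
(geometric mean 30 mg eq., geometric SD 1.5) and is negligible by the
analysed dosing period a year later.  The dose fractions `f1, f3` run
through a positive lognormal latent `kappa` with two selectable
back-transforms:

* `paper_logistic`: `theta = 1/(1+exp(-kappa))` — confines fractions to
  (0.5, 1) because `kappa > 0`;
* `odds_ratio`: `theta = kappa/(1+kappa)` — the self-consistent odds
  reading under which the latent location `mu/(1-mu)` maps back to the
  population mean fraction `mu`.

The two printed transform conventions these implement do not compose
consistently with each other, so the choice is explicit configuration.
The shipped profile uses `odds_ratio` because the case study's physics
requires a small rapid-release fraction (f3 ≈ 0.1, so the slow depot
carries ~90% of each dose and its maximum release rate `kas3_max` is the
most influential release parameter); that regime is unreachable under
`paper_logistic`.

The test formulation differs from the reference only through `delta`, six
multiplicative shifts on the population locations of
`(f3, kas3_max, kar3_max, kas3_50, kar3_50, gamma)` — for `f3` the shift
acts on the latent `kappa` location.

## Shipped profile (`paliperidone-lai-v1`)

The original model's numerical parameter values are published only inside
supplementary model code that this package does not redistribute.  The
profile therefore carries placeholder values, fixed once, chosen so the
simulations sit in the documented qualitative regime:

| quantity | value | why |
|---|---|---|
| CL, V | 120 L/day, 400 L | paliperidone-scale clearance/volume; ~48 ng/mL average at 525 mg eq./13 weeks |
| f3 (mean) | 0.10 | slow depot dominates exposure |
| kas3_max, kas3_50, γ | 6.5 mg/day, 150 mg, 1.8 | slow depot ~75-80% saturated at steady state, releasing over months |
| kar3_max, kar3_50 | 12 mg/day, 60 mg | rapid depot (~52 mg/dose) drains in ~2 weeks |
| f1 (mean), tl1, ka1 | 0.15, 2 days, 0.02/day | PP1M burst then ~58-day release half-life |
| log-SDs | CL 0.45, V 0.35, ka1/kar3_50/κ 0.4, kas3 0.3 | exposure CV ~50-57% |
| residual σ | 0.2 (log scale) | ~20% proportional assay/model error |

Dosing: four monthly 150 mg eq. PP1M injections (days 0–84), then four
3-monthly 525 mg eq. PP3M injections (weeks 15, 28, 41, 54).  The
analysis interval is the 11-week span from the final injection (weeks
54–65); the default sampling schedule is weeks 54, 55, 57, 59, 63 with
the variant 54, 55, 57, 61, 65 available by name (both schedules are in
circulation for this design and neither is privileged).

Under these conditions a 130/arm trial shows Cmax/AUC CVs of ~53–57%, a
5% increase of `kas3_max` moves typical-subject exposure by ~2%, and the
population GMR response to `delta2` is ~+21% (Cmax) and ~+9% (AUC) at
`delta2 = 1.42`.

## Recalibration

Only `delta2` (the `kas3_max` shift) is estimated, with a vague lognormal
prior (geometric mean 1, geometric SD 2); all other shift components stay
fixed and the population means, variances and residual variance are pinned
at their configured central values — updating them from a 50-subject trial
would be meaningless when the reference arm is drawn from those priors by
construction.  The subject-level parameters (9 per subject) are estimated
jointly, 451 parameters for the 25+25 design.

The sampler is random-walk Metropolis on the log scale.  Each subject is
one block (its nine parameters proposed jointly); subjects are
conditionally independent given `delta2`, so all subject blocks are
proposed and accepted in parallel from a single vectorised ODE evaluation
— the same kernel as sequential per-subject updates, at a fraction of the
cost.  `delta2` has its own block and touches no ODE: it enters only
through the test arm's `kas3_max` population density and its prior.
Proposal scales adapt every 50 iterations during burn-in toward ~28%
(subjects) / ~35% (`delta2`) acceptance and are frozen afterwards.  Chains
start overdispersed around the population locations.  Convergence is
monitored with the between/within-chain potential scale reduction factor;
R-hat < 1.1 is treated as sufficient for `delta2`, while weakly-informed
per-subject nuisance parameters may converge more slowly without
affecting the `delta2` summaries (verified by the recovery experiments).

Default chain layout: 4 chains × 10,000 iterations, first 2,500
discarded.  The acceptance experiments use 4 × 2,000 (burn-in 1,000) at
100/arm, where one run takes ~70 s and the 95% credibility interval
covers a true `delta2` = 1.3 in 5/5 seeded replicates.

## Decision machinery

TOST uses the classical CI-inclusion form on log metrics with a pooled
two-sample variance (Welch available): equivalence iff the 90% CI of
`exp(mean log difference)` lies in [0.8, 1.25].  Overall pass requires
both Cmax and partial AUC.  Workflow B simulates trials with *noise-free
model-integrated* exposures — measurement error was already accounted for
during calibration and re-introducing it would only blur the
posterior-predictive ratios.

Boundary placement for type-I experiments multiplies every test-arm
concentration by the limit, which places the true GMR of *both* metrics
exactly on the limit (NCA Cmax and trapezoid AUC are homogeneous of
degree 1 in concentrations).  A consequence worth knowing: the joint
type-I error is then roughly `alpha * P(second metric passes | first
does)`.  With the high Cmax/AUC correlation of a slow-release depot
(rho ≈ 0.94 here) that product is ~3–4%, not far below the single-metric
size of ~5% — the "both metrics at the limit" placement is close to the
worst case.  A shift-based placement, where only the most elastic metric
reaches the limit and the other stays inside, gives much smaller joint
rates; both views are legitimate, and the scaling placement is the one
implemented because it is exact and metric-symmetric.

Safe-space mode A samples `delta ~ U[0.5, 2]^6` per trial and records the
full-trial TOST verdict (fuzzy, blurred by trial noise and test power);
mode B fixes `(delta1, delta2)` on a grid, ignores posterior uncertainty,
and declares a point safe iff the *mean* (dCmax, dAUC) over its trials
lies within the limits (a probability-rule variant is available), with
optional bisection refinement of the boundary along `delta2`.

## Synthetic data and what the tests show

The trial simulator doubles as the package's data generator; no external
data are read.  It emulates parallel-design LAI trials with lognormal
inter-subject variability and lognormal residual error.  It does *not*
emulate covariate effects, random-effect correlations, inter-occasion
variability, dropout, or mid-trial dose adjustment — so green tests
demonstrate the statistical machinery under the stated hierarchical
model, not robustness to the messiness of real clinical data.  Because
the structural parameter values are placeholders, quantities tied to the
original numbers (e.g. published single-realization GMRs or
posterior-predictive tail probabilities) are not reproduced; the tests
assert distributional and operating-characteristic properties instead.

## Numerical choices and scales

* Seeding: numpy `SeedSequence`/`default_rng` everywhere; chains and
  stages derive child streams from one master seed; identical seeds give
  bit-identical datasets, chains and output files.
* Degenerate inputs: zero variances collapse sampling to the population
  locations; zero residual SD returns noise-free measurements; zero-dose
  regimens decay `Qc0` monoexponentially; TOST refuses arms with fewer
  than 2 subjects or zero variance in both arms; NCA needs ≥ 2 points in
  the interval.
* Quantiles use numpy's default linear interpolation; credibility
  intervals are equal-tailed 2.5/97.5%.
* Problem sizes in the test suite are chosen to keep the whole suite near
  ten minutes: 100 replicates for power, 200 for type-I, 200 trials ×
  200/arm for workflow-B calibration, a 5 × 5 grid × 50 trials/point for
  safe-space consistency, and five seeds × (4 × 2,000) chains for
  `delta2` recovery.  `scripts/acceptance.py` uses 1,200 (type-I) and 150
  (power) replicates at 130/arm.

## Known limitations

* The shipped parameter values are calibrated placeholders; absolute
  exposures and elasticities will differ from the original products.
* Only `delta2` is estimated during recalibration; joint estimation of
  several shift components would need stronger designs than 25/arm.
* Parallel designs only (no cross-over, no replicate designs, no
  reference-scaled average BE), and no Cmin/alternative partial-AUC
  metrics beyond the last-interval AUC.
* The `paper_logistic` transform is retained for completeness but cannot
  represent fractions below 0.5.
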