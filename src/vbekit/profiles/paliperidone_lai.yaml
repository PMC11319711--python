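# Profile: paliperidone-lai-v1
#
# Population PK configuration for the paliperidone long-acting injectable
# case study (1-month run-in product + 3-month depot product).
#
# NOTE ON PROVENANCE: the published structural and population parameter
# values for these products live in supplementary model code that is not
# redistributed here.  The values below are PLACEHOLDERS chosen so that the
# simulated kinetics sit in the documented qualitative regime: plasma
# concentrations of a few tens of ng/mL at steady state, terminal profiles
# spanning months, ~50-55% inter-subject CV on Cmax and partial AUC, and
# the slow-depot maximum release rate (kas3_max) as the most influential
# drug-release parameter.  They are configuration, not ground truth.
profile: paliperidone-lai-v1
time_unit: day

structural:
  tl1_days: 2.0            # zero-order release window of the 1-month product

population:
  # odds_ratio keeps the latent-odds location consistent with the population
  # mean fraction and admits the small rapid-release fraction (f3 ~ 0.1)
  # that makes the slow depot, hence kas3_max, dominate exposure.
  transform: odds_ratio
  mu:                      # geometric means (units: 1/day, mg, mg/day, L/day, L)
    ka1: 0.02
    kar3_50: 60.0
    kas3_max: 6.5
    kas3_50: 150.0
    CL: 120.0
    V: 400.0
  shared:                  # identical for all subjects
    kar3_max: 12.0         # mg/day
    gamma: 1.8
  fraction_means:          # population mean fractions (latent odds location)
    f1: 0.15
    f3: 0.10
  sigma_log:               # log-space SDs (for f1/f3: SD of log kappa)
    ka1: 0.4
    kar3_50: 0.4
    kas3_max: 0.3
    kas3_50: 0.3
    CL: 0.45
    V: 0.35
    f1: 0.4
    f3: 0.4
  qc0:
    geometric_mean: 30.0   # mg eq. pre-trial body burden
    geometric_sd: 1.5
  residual_sd_log: 0.2
  delta: [1.0, 1.05, 1.0, 1.0, 1.0, 1.0]   # (f3, kas3_max, kar3_max, kas3_50, kar3_50, gamma)

designs:
  abbreviated: {n_per_arm: 25, schedule: weeks_54_63}
  large: {n_per_arm: 130, schedule: weeks_54_63}
  safe_space: {n_per_arm: 130, n_trials: 1000}

mcmc:
  n_chains: 4
  n_iter: 10000
  n_burnin: 2500
  delta2_prior: {geometric_mean: 1.0, geometric_sd: 2.0}

decision:
  limits: [0.8, 1.25]
  alpha: 0.05
  threshold: 0.95

seed: 20240730
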