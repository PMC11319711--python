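"""Bayesian recalibration of the formulation shift from abbreviated-trial data.

The only population-level unknown is ``delta2``, the multiplicative
test/reference shift of the slow-depot maximum release rate ``kas3_max``;
the other shift components stay fixed (1 by default) and the population
geometric means, variances and residual variance are pinned at their
configured central values.  The subject-level parameters

    f1, f3 (latent kappa), ka1, kar3_50, kas3_max, kas3_50, CL, V, Qc0

of every trial participant are estimated jointly with ``delta2`` — for a
25 + 25 trial that is 9 x 50 + 1 = 451 parameters.

Sampling is component-wise random-walk Metropolis on the log scale.  Each
subject forms one proposal block (its nine log-parameters move together);
because subjects are conditionally independent given ``delta2``, all
subject blocks are proposed and accepted/rejected simultaneously, which
lets a single vectorised ODE evaluation serve the whole sweep.  ``delta2``
has its own block and needs no ODE work: it enters the posterior only
through the population density of the test arm's ``kas3_max`` values and
its lognormal prior.  Proposal scales adapt toward a 20-40% acceptance
rate during burn-in and are frozen afterwards, preserving the stationary
distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import population_model as pm
from .structural_pk import THETA_FIELDS, _pk_kernel, build_grid
from .trial_simulator import ConcentrationDataset, TrialDesign

logger = logging.getLogger(__name__)

#: estimated per-subject quantities, stored as log values
Z_FIELDS = ("kappa_f1", "kappa_f3", "ka1", "kar3_50", "kas3_max",
            "kas3_50", "CL", "V", "Qc0")
_KSM = Z_FIELDS.index("kas3_max")

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; the default chain layout follows common practice
    for this model class (4 chains, long run, first quarter discarded)."""

    n_chains: int = 4
    n_iter: int = 10_000
    n_burnin: int = 2_500
    seed: int = 0
    delta2_prior_gm: float = 1.0
    delta2_prior_gsd: float = 2.0
    subject_scale: float = 0.12      # initial per-block proposal multiplier
    delta2_scale: float = 0.1
    adapt_interval: int = 50
    target_acceptance: float = 0.28
    dt_max: float = 3.0              # likelihood ODE step bound (days)
    store_subjects: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence checks")
        if not 0 <= self.n_burnin < self.n_iter:
            raise ValueError("n_burnin must satisfy 0 <= n_burnin < n_iter")
        if self.subject_scale <= 0 or self.delta2_scale <= 0:
            raise ValueError("proposal scales must be positive")
        if self.delta2_prior_gsd <= 1.0:
            raise ValueError("delta2 prior geometric SD must exceed 1")


@dataclass
class MCMCResult:
    """Post-burn-in draws plus diagnostics.

    ``delta2``: (n_chains, n_kept); ``subjects``: (n_chains, n_kept,
    n_subjects, 9) in :data:`Z_FIELDS` order (natural scale), or None when
    subject storage is off.
    """

    delta2: np.ndarray
    subjects: np.ndarray | None
    subject_ids: list[str]
    arms: np.ndarray
    acceptance: dict
    rhat: dict
    config: MCMCConfig

    @property
    def delta2_flat(self) -> np.ndarray:
        return self.delta2.reshape(-1)

    def summary(self) -> dict:
        s = posterior_summary(self.delta2_flat)
        s["rhat"] = self.rhat["delta2"]
        return s


# ---------------------------------------------------------------------------
# posterior pieces
# ---------------------------------------------------------------------------

class RecalibrationProblem:
    """Data, priors and cached solver grid for one recalibration run.

    The measurement model fixes the residual log-variance at the
    population value; the subject-parameter population densities use the
    configured central locations, with the test arm's ``kas3_max``
    location shifted by the current ``delta2``.
    """

    def __init__(self, data: ConcentrationDataset | None,
                 pop: pm.PopulationParams, regimen,
                 dt_max: float = 3.0,
                 arms: Sequence[str] | None = None):
        if data is not None and len(data.data):
            wide = data.data.pivot_table(index=["subject", "arm"],
                                         columns="time_days",
                                         values="conc_ng_per_ml")
            if wide.isna().any().any():
                raise ValueError("recalibration expects a rectangular dataset"
                                 " (every subject sampled at the same times)")
            self.subject_ids = [s for s, _ in wide.index]
            self.is_test = np.array([a == pm.TEST for _, a in wide.index])
            self.times = np.asarray(wide.columns, dtype=float)
            self.log_obs = np.log(wide.to_numpy(dtype=float))
        else:
            if arms is None:
                raise ValueError("an empty problem needs an explicit arm list")
            self.subject_ids = [f"S{i + 1:03d}" for i in range(len(arms))]
            self.is_test = np.array([a == pm.TEST for a in arms])
            self.times = np.empty(0)
            self.log_obs = np.empty((len(self.subject_ids), 0))
        self.n_sub = len(self.subject_ids)
        self.n_nonfinite = 0
        self.pop = pop
        self.sigma = pop.resid_sd_log
        if self.times.size and self.sigma <= 0:
            raise ValueError("recalibration requires a positive residual SD")
        self.grid = (build_grid(regimen, pop.tl1, self.times, dt_max)
                     if self.times.size else None)

        # delta components other than delta2 stay at their configured values
        self.fixed_delta = np.asarray(pop.delta, dtype=float).copy()
        self.fixed_delta[1] = 1.0

        loc_ref = pm.arm_locations(pop, pm.REFERENCE)
        loc_test = pm.apply_formulation_shift(
            {k: loc_ref[k] for k in pm.DELTA_ORDER}, self.fixed_delta)
        base_mean = {
            "kappa_f1": np.log(loc_ref["f1"]),
            "kappa_f3": np.where(self.is_test, np.log(loc_test["f3"]),
                                 np.log(loc_ref["f3"])),
            "ka1": np.log(pop.mu["ka1"]),
            "kar3_50": np.where(self.is_test, np.log(loc_test["kar3_50"]),
                                np.log(loc_ref["kar3_50"])),
            "kas3_max": np.log(pop.mu["kas3_max"]),  # + log delta2 for test
            "kas3_50": np.where(self.is_test, np.log(loc_test["kas3_50"]),
                                np.log(loc_ref["kas3_50"])),
            "CL": np.log(pop.mu["CL"]),
            "V": np.log(pop.mu["V"]),
            "Qc0": np.log(pop.qc0_gm),
        }
        self.prior_mean = np.column_stack(
            [np.broadcast_to(base_mean[f], (self.n_sub,)) for f in Z_FIELDS])
        sd = {
            "kappa_f1": pop.sigma_log["f1"], "kappa_f3": pop.sigma_log["f3"],
            "ka1": pop.sigma_log["ka1"], "kar3_50": pop.sigma_log["kar3_50"],
            "kas3_max": pop.sigma_log["kas3_max"],
            "kas3_50": pop.sigma_log["kas3_50"], "CL": pop.sigma_log["CL"],
            "V": pop.sigma_log["V"], "Qc0": np.log(pop.qc0_gsd),
        }
        self.prior_sd = np.array([sd[f] for f in Z_FIELDS])
        if np.any(self.prior_sd <= 0):
            raise ValueError("all population log-SDs must be positive "
                             "for recalibration")
        # shared structural values per subject (test arm keeps fixed shifts)
        self.kar3_max = np.where(self.is_test, loc_test["kar3_max"],
                                 loc_ref["kar3_max"])
        self.gamma = np.where(self.is_test, loc_test["gamma"],
                              loc_ref["gamma"])

    # -- likelihood ---------------------------------------------------
    def theta_from_z(self, z: np.ndarray) -> np.ndarray:
        th = np.empty((self.n_sub, len(THETA_FIELDS)))
        th[:, 0] = pm.fraction_transform(np.exp(z[:, 0]), self.pop.transform)
        th[:, 1] = pm.fraction_transform(np.exp(z[:, 1]), self.pop.transform)
        th[:, 2] = np.exp(z[:, 2])    # ka1
        th[:, 3] = self.kar3_max
        th[:, 4] = np.exp(z[:, 3])    # kar3_50
        th[:, 5] = np.exp(z[:, 4])    # kas3_max
        th[:, 6] = np.exp(z[:, 5])    # kas3_50
        th[:, 7] = self.gamma
        th[:, 8] = np.exp(z[:, 6])    # CL
        th[:, 9] = np.exp(z[:, 7])    # V
        th[:, 10] = np.exp(z[:, 8])   # Qc0
        return th

    def loglik(self, z: np.ndarray) -> np.ndarray:
        """Per-subject lognormal measurement log-likelihood."""
        if self.grid is None:
            return np.zeros(self.n_sub)
        g = self.grid
        conc, _, status, _ = _pk_kernel(self.theta_from_z(z), g.t, g.add1,
                                        g.add3, g.xfer, g.zo, g.out_idx,
                                        False)
        ll = np.full(self.n_sub, -np.inf)
        ok = status == 0
        n_bad = int((~ok).sum())
        if n_bad:
            # warn once per problem; further events at debug level
            level = logging.DEBUG if self.n_nonfinite else logging.WARNING
            logger.log(level, "non-finite model prediction for %d subject "
                       "proposal(s); assigned -inf posterior", n_bad)
            self.n_nonfinite += n_bad
        if not np.any(ok):
            return ll
        with np.errstate(divide="ignore", invalid="ignore"):
            logc = np.log(conc[ok])
            resid = self.log_obs[ok] - logc
            term = (-np.log(self.sigma) - 0.5 * _LOG_2PI - self.log_obs[ok]
                    - 0.5 * (resid / self.sigma) ** 2)
            vals = term.sum(axis=1)
        vals[~np.isfinite(vals)] = -np.inf
        ll[ok] = vals
        return ll

    # -- priors -------------------------------------------------------
    def logprior_subjects(self, z: np.ndarray, log_d2: float) -> np.ndarray:
        mean = self.prior_mean.copy()
        mean[self.is_test, _KSM] += log_d2
        r = (z - mean) / self.prior_sd
        return (-0.5 * r * r - np.log(self.prior_sd)
                - 0.5 * _LOG_2PI).sum(axis=1)

    def pop_term_delta2(self, z: np.ndarray, log_d2: float) -> float:
        """The only delta2-dependent population term (test-arm kas3_max)."""
        m = self.prior_mean[self.is_test, _KSM] + log_d2
        r = (z[self.is_test, _KSM] - m) / self.prior_sd[_KSM]
        return float(np.sum(-0.5 * r * r))


def log_posterior(delta2: float, z: np.ndarray,
                  problem: RecalibrationProblem,
                  prior_gm: float = 1.0, prior_gsd: float = 2.0) -> float:
    """Joint log-posterior of ``delta2`` and all subject log-parameters.

    Sum of the lognormal measurement likelihood, the population densities
    of the subject parameters (test-arm ``kas3_max`` location shifted by
    ``delta2``), and the lognormal ``delta2`` prior.  Out-of-domain values
    return -inf.
    """
    if delta2 <= 0:
        return -np.inf
    log_d2 = np.log(delta2)
    s = np.log(prior_gsd)
    lp_d2 = (-np.log(s) - 0.5 * _LOG_2PI - log_d2
             - 0.5 * ((log_d2 - np.log(prior_gm)) / s) ** 2)
    total = (problem.loglik(z).sum()
             + problem.logprior_subjects(z, log_d2).sum() + lp_d2)
    return float(total) if np.isfinite(total) else -np.inf


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def random_walk_metropolis(logpost, x0: np.ndarray, scale, n_iter: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Plain random-walk Metropolis on an arbitrary target (used for
    reduced/conjugate cross-checks; the trial sampler has its own loop)."""
    x = np.atleast_1d(np.asarray(x0, dtype=float))
    lp = logpost(x)
    draws = np.empty((n_iter, x.size))
    for i in range(n_iter):
        prop = x + scale * rng.standard_normal(x.size)
        lp_p = logpost(prop)
        if np.log(rng.random()) < lp_p - lp:
            x, lp = prop, lp_p
        draws[i] = x
    return draws


def run_mcmc(config: MCMCConfig, data: ConcentrationDataset,
             pop: pm.PopulationParams, design: TrialDesign | None = None,
             regimen=None, quiet: bool = True) -> MCMCResult:
    """Metropolis-Hastings recalibration of ``delta2`` and the subject
    parameters given abbreviated-trial concentrations."""
    from .trial_simulator import standard_regimen
    if regimen is None:
        regimen = design.regimen if design is not None else standard_regimen()
    prob = RecalibrationProblem(data, pop, regimen, config.dt_max)
    n_kept = config.n_iter - config.n_burnin
    prior_lgm = np.log(config.delta2_prior_gm)
    prior_lsd = np.log(config.delta2_prior_gsd)

    delta2_draws = np.empty((config.n_chains, n_kept))
    subj_draws = (np.empty((config.n_chains, n_kept, prob.n_sub,
                            len(Z_FIELDS)), dtype=np.float32)
                  if config.store_subjects else None)
    acc_subject = np.zeros(config.n_chains)

    ss = np.random.SeedSequence(config.seed)
    for chain, child in enumerate(ss.spawn(config.n_chains)):
        rng = np.random.default_rng(child)
        # overdispersed start around the population locations
        z = (prob.prior_mean
             + 0.5 * prob.prior_sd * rng.standard_normal(
                 (prob.n_sub, len(Z_FIELDS))))
        log_d2 = prior_lgm + 0.5 * prior_lsd * rng.standard_normal()

        scale = np.full(prob.n_sub, config.subject_scale)
        d2_scale = config.delta2_scale
        ll = prob.loglik(z)
        lp = prob.logprior_subjects(z, log_d2)
        win_acc = np.zeros(prob.n_sub)
        win_acc_d2 = 0.0

        for it in range(config.n_iter):
            # -- all subject blocks at once -------------------------------
            prop = z + (scale[:, None] * prob.prior_sd[None, :]
                        * rng.standard_normal(z.shape))
            ll_p = prob.loglik(prop)
            lp_p = prob.logprior_subjects(prop, log_d2)
            with np.errstate(invalid="ignore"):
                logr = ll_p + lp_p - ll - lp
            accept = np.log(rng.random(prob.n_sub)) < logr
            z[accept] = prop[accept]
            ll[accept] = ll_p[accept]
            lp[accept] = lp_p[accept]
            win_acc += accept

            # -- delta2 block ---------------------------------------------
            prop_d2 = log_d2 + d2_scale * rng.standard_normal()
            logr_d2 = (prob.pop_term_delta2(z, prop_d2)
                       - prob.pop_term_delta2(z, log_d2)
                       - 0.5 * ((prop_d2 - prior_lgm) / prior_lsd) ** 2
                       + 0.5 * ((log_d2 - prior_lgm) / prior_lsd) ** 2)
            if np.log(rng.random()) < logr_d2:
                log_d2 = prop_d2
                lp = prob.logprior_subjects(z, log_d2)
                win_acc_d2 += 1.0

            # -- burn-in adaptation ---------------------------------------
            if (it + 1) % config.adapt_interval == 0:
                if it < config.n_burnin:
                    rate = win_acc / config.adapt_interval
                    scale *= np.exp(rate - config.target_acceptance)
                    np.clip(scale, 1e-3, 10.0, out=scale)
                    rate_d2 = win_acc_d2 / config.adapt_interval
                    d2_scale *= np.exp(rate_d2 - 0.35)
                    d2_scale = float(np.clip(d2_scale, 1e-4, 10.0))
                elif not quiet and (it + 1) % 1000 == 0:
                    logger.info("chain %d iteration %d", chain, it + 1)
                win_acc[:] = 0.0
                win_acc_d2 = 0.0

            if it >= config.n_burnin:
                k = it - config.n_burnin
                delta2_draws[chain, k] = np.exp(log_d2)
                if subj_draws is not None:
                    subj_draws[chain, k] = np.exp(z)
                acc_subject[chain] += accept.mean()
        acc_subject[chain] /= n_kept

    # post-burn-in delta2 acceptance measured from the draws themselves
    moves = np.mean(np.diff(delta2_draws, axis=1) != 0, axis=1)
    if np.any(moves == 0):
        logger.warning("a chain never moved delta2 after burn-in; "
                       "check proposal scales")

    rhat = {"delta2": gelman_rubin(delta2_draws)}
    if subj_draws is not None:
        flat = np.log(subj_draws.reshape(config.n_chains, n_kept, -1))
        rhat_subj = gelman_rubin_stack(flat)
        rhat["subjects_max"] = float(np.nanmax(rhat_subj))
        rhat["subjects"] = rhat_subj.reshape(prob.n_sub, len(Z_FIELDS))
    return MCMCResult(delta2=delta2_draws, subjects=subj_draws,
                      subject_ids=prob.subject_ids,
                      arms=np.where(prob.is_test, pm.TEST, pm.REFERENCE),
                      acceptance={"subjects": acc_subject.tolist(),
                                  "delta2": moves.tolist()},
                      rhat=rhat, config=config)


# ---------------------------------------------------------------------------
# diagnostics & summaries
# ---------------------------------------------------------------------------

def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor from between/within-chain variance.

    ``chains`` has shape (n_chains, n_draws).  With zero within-chain
    variance the statistic is undefined and NaN is returned.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful diagnostic")
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = chains.mean(axis=1).var(ddof=1)
    if w == 0:
        return float("nan")
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


def gelman_rubin_stack(chains: np.ndarray) -> np.ndarray:
    """Vectorised :func:`gelman_rubin` over the trailing parameter axis
    of a (n_chains, n_draws, n_params) array."""
    m, n, _ = chains.shape
    w = chains.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = chains.mean(axis=1).var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(((n - 1) / n * w + b_over_n) / w)
    out[w == 0] = np.nan
    return out


def posterior_summary(draws: np.ndarray) -> dict:
    """Geometric mean / geometric SD / equal-tailed 95% credibility interval.

    Quantiles use numpy's default linear interpolation.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 100:
        raise ValueError("need at least 100 draws for a summary")
    if np.any(draws <= 0):
        raise ValueError("posterior summaries are defined for positive draws")
    logs = np.log(draws)
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return {"gm": float(np.exp(logs.mean())),
            "gsd": float(np.exp(logs.std(ddof=1))),
            "cri95": (float(lo), float(hi))}
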