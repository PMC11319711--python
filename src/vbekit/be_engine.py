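"""Bioequivalence decision machinery for both assessment workflows.

Workflow A (data-based): a simulated trial is analysed like a real one —
per-subject NCA metrics, then a two one-sided-tests (TOST) procedure on
the log metrics; equivalence is declared when the 90% confidence interval
of each geometric-mean ratio (Cmax and partial AUC) lies inside the
0.8-1.25 limits.

Workflow B (fully Bayesian, model-integrated): the posterior of the
formulation shift ``delta2`` is propagated through many large virtual
trials to a posterior-predictive sample of the population GMR pair
(dCmax, dAUC); bioequivalence is declared when the probability that both
ratios fall inside the limits reaches a threshold (default 0.95).
Workflow-B exposures are noise-free model-integrated metrics — the
measurement error was already accounted for during calibration.

The module also provides power / type-I simulation, a local sensitivity
ranking of the six shift components, and safe-space mapping in both
modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import population_model as pm
from . import structural_pk as spk
from . import trial_simulator as ts
from .exceptions import VbeError
from .trial_simulator import ConcentrationDataset, TrialDesign

BE_LIMITS = (0.8, 1.25)
METRICS = ("cmax", "auc")


# ---------------------------------------------------------------------------
# TOST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TostMetric:
    """TOST outcome for a single exposure metric."""

    gmr: float
    ci90: tuple[float, float]
    passed: bool
    limits: tuple[float, float] = BE_LIMITS
    alpha: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.ci90
        if not lo <= self.gmr <= hi:
            raise ValueError("GMR must lie inside its confidence interval")


@dataclass(frozen=True)
class TOSTResult:
    """Per-metric TOST outcomes; overall pass requires both metrics."""

    cmax: TostMetric
    auc: TostMetric

    @property
    def passed(self) -> bool:
        return self.cmax.passed and self.auc.passed

    def to_dict(self) -> dict:
        return {m: {"gmr": getattr(self, m).gmr,
                    "ci90": list(getattr(self, m).ci90),
                    "pass": bool(getattr(self, m).passed)}
                for m in METRICS} | {"pass": bool(self.passed)}


def tost(log_test: Sequence[float], log_ref: Sequence[float],
         alpha: float = 0.05, limits: tuple[float, float] = BE_LIMITS,
         variance: str = "pooled") -> TostMetric:
    """Two one-sided tests on log metrics for a parallel design.

    Equivalence holds iff the two-sided 100(1-2*alpha)% CI of
    ``exp(mean(log_test) - mean(log_ref))`` lies inside ``limits``
    (the classical CI-inclusion formulation of TOST).
    """
    x = np.asarray(log_test, dtype=float)
    y = np.asarray(log_ref, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each arm needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("log metrics must be finite")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("degenerate data: zero variance in both arms")
    d = x.mean() - y.mean()
    if variance == "pooled":
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    elif variance == "welch":
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        raise ValueError(f"unknown variance option {variance!r}")
    tq = stats.t.ppf(1.0 - alpha, df)
    lo, hi = np.exp(d - tq * se), np.exp(d + tq * se)
    passed = bool(limits[0] <= lo and hi <= limits[1])
    return TostMetric(gmr=float(np.exp(d)), ci90=(float(lo), float(hi)),
                      passed=passed, limits=limits, alpha=alpha)


def tost_from_metrics(metrics: pd.DataFrame, alpha: float = 0.05,
                      limits: tuple[float, float] = BE_LIMITS,
                      variance: str = "pooled") -> TOSTResult:
    """Apply :func:`tost` to the cmax and auc columns of an NCA table."""
    out = {}
    for m in METRICS:
        lt = np.log(metrics.loc[metrics["arm"] == pm.TEST, m])
        lr = np.log(metrics.loc[metrics["arm"] == pm.REFERENCE, m])
        out[m] = tost(lt, lr, alpha=alpha, limits=limits, variance=variance)
    return TOSTResult(cmax=out["cmax"], auc=out["auc"])


def be_decision_workflow_A(dataset: ConcentrationDataset,
                           interval: tuple[float, float] = ts.ANALYSIS_INTERVAL,
                           alpha: float = 0.05,
                           limits: tuple[float, float] = BE_LIMITS,
                           variance: str = "pooled") -> TOSTResult:
    """Data-based decision: NCA per subject, then TOST on both metrics."""
    metrics = ts.nca_table(dataset, interval)
    return tost_from_metrics(metrics, alpha=alpha, limits=limits,
                             variance=variance)


# ---------------------------------------------------------------------------
# workflow B
# ---------------------------------------------------------------------------

@dataclass
class RatioSamples:
    """Monte-Carlo draws of the population GMR pair (dCmax, dAUC).

    One draw per simulated trial: the ratio of test over reference arm
    geometric means of the noise-free model-integrated exposures.
    """

    dcmax: np.ndarray
    dauc: np.ndarray
    n_per_arm: int
    delta2_source: str = "posterior"

    def __post_init__(self) -> None:
        self.dcmax = np.asarray(self.dcmax, dtype=float)
        self.dauc = np.asarray(self.dauc, dtype=float)
        if self.dcmax.shape != self.dauc.shape or self.dcmax.ndim != 1:
            raise ValueError("ratio draws must be paired 1-D arrays")
        if np.any(self.dcmax <= 0) or np.any(self.dauc <= 0):
            raise ValueError("ratio draws must be strictly positive")

    @property
    def n_trials(self) -> int:
        return self.dcmax.size


@dataclass(frozen=True)
class BEDecision:
    """Verdict of either workflow with the workflow-B tail probabilities."""

    workflow: str
    passed: bool
    p_both_within: float | None = None
    p_cmax_above: float | None = None
    p_cmax_below: float | None = None
    p_auc_above: float | None = None
    p_auc_below: float | None = None
    threshold: float | None = None
    limits: tuple[float, float] = BE_LIMITS

    def to_dict(self) -> dict:
        return {"workflow": self.workflow, "pass": bool(self.passed),
                "limits": list(self.limits),
                **{k: v for k, v in (
                    ("p_both_within", self.p_both_within),
                    ("p_cmax_above", self.p_cmax_above),
                    ("p_cmax_below", self.p_cmax_below),
                    ("p_auc_above", self.p_auc_above),
                    ("p_auc_below", self.p_auc_below),
                    ("threshold", self.threshold)) if v is not None}}


def _trial_ratio(pop: pm.PopulationParams, regimen, interval: tuple,
                 n_per_arm: int, rng: np.random.Generator,
                 n_grid: int = 100, dt_max: float = 1.0) -> tuple[float, float]:
    """Population GMRs of one noise-free model-integrated virtual trial."""
    out = {}
    for arm in pm.ARMS:
        theta = pm.sample_arm(pop, arm, n_per_arm, rng)
        cmax, auc = spk.exposure_population(theta, regimen, pop.tl1, interval,
                                            n_grid=n_grid, dt_max=dt_max)
        out[arm] = (np.log(cmax).mean(), np.log(auc).mean())
    dc = np.exp(out[pm.TEST][0] - out[pm.REFERENCE][0])
    da = np.exp(out[pm.TEST][1] - out[pm.REFERENCE][1])
    return dc, da


def posterior_predictive_ratios(delta2, pop: pm.PopulationParams,
                                n_trials: int, n_per_arm: int,
                                rng: np.random.Generator | int | None = None,
                                regimen=None,
                                interval: tuple = ts.ANALYSIS_INTERVAL,
                                dt_max: float = 1.0) -> RatioSamples:
    """Posterior-predictive sample of the (dCmax, dAUC) ratio pair.

    ``delta2`` may be an array of posterior draws (resampled per trial), a
    ``(gm, gsd)`` lognormal summary, or a scalar point mass.  Each trial
    draws one ``delta2``, samples fresh subjects in both arms with the
    shift applied to the test arm, and takes the ratio of arm geometric
    means of the model-integrated exposures.
    """
    if n_trials < 1 or n_per_arm < 2:
        raise ValueError("need n_trials >= 1 and n_per_arm >= 2")
    rng = np.random.default_rng(rng)
    if regimen is None:
        regimen = ts.standard_regimen()

    if isinstance(delta2, (int, float)):
        draws = np.full(n_trials, float(delta2))
        source = "point"
    elif isinstance(delta2, tuple):
        gm, gsd = delta2
        if gm <= 0 or gsd < 1:
            raise ValueError("invalid lognormal summary for delta2")
        draws = gm * np.exp(np.log(gsd) * rng.standard_normal(n_trials))
        source = "lognormal_summary"
    else:
        arr = np.asarray(delta2, dtype=float).ravel()
        if arr.size == 0 or np.any(arr <= 0):
            raise ValueError("delta2 posterior draws must be positive")
        draws = rng.choice(arr, size=n_trials, replace=True)
        source = "posterior"

    dcmax = np.empty(n_trials)
    dauc = np.empty(n_trials)
    for t in range(n_trials):
        popd = pop.with_delta((pop.delta[0], draws[t], *pop.delta[2:]))
        dcmax[t], dauc[t] = _trial_ratio(popd, regimen, interval, n_per_arm,
                                         rng, dt_max=dt_max)
    return RatioSamples(dcmax=dcmax, dauc=dauc, n_per_arm=n_per_arm,
                        delta2_source=source)


def be_decision_workflow_B(ratios: RatioSamples, threshold: float = 0.95,
                           limits: tuple[float, float] = BE_LIMITS) -> BEDecision:
    """Probabilistic decision: pass iff P(both ratios within limits) >= threshold."""
    if ratios.n_trials < 100:
        raise ValueError("need at least 100 ratio draws for a decision")
    lo, hi = limits
    within = ((ratios.dcmax >= lo) & (ratios.dcmax <= hi)
              & (ratios.dauc >= lo) & (ratios.dauc <= hi))
    p_both = float(within.mean())
    return BEDecision(
        workflow="B", passed=bool(p_both >= threshold), p_both_within=p_both,
        p_cmax_above=float((ratios.dcmax > hi).mean()),
        p_cmax_below=float((ratios.dcmax < lo).mean()),
        p_auc_above=float((ratios.dauc > hi).mean()),
        p_auc_below=float((ratios.dauc < lo).mean()),
        threshold=threshold, limits=limits)


# ---------------------------------------------------------------------------
# power / type-I error
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerResult:
    pass_fraction: float
    mc_se: float
    n_reps: int
    placement: str

    def to_dict(self) -> dict:
        return {"pass_fraction": self.pass_fraction, "mc_se": self.mc_se,
                "n_reps": self.n_reps, "placement": self.placement}


def power_type1(design: TrialDesign, pop: pm.PopulationParams,
                placement: str = "null", n_reps: int = 100,
                rng: np.random.Generator | int | None = None,
                boundary: float = 1.25, delta=None, alpha: float = 0.05,
                limits: tuple[float, float] = BE_LIMITS) -> PowerResult:
    """Fraction of simulated trials declared bioequivalent by workflow A.

    ``placement`` fixes the true exposure ratio:

    * ``"null"`` — identical formulations (all delta components 1);
      the pass fraction estimates power at perfect equivalence.
    * ``"boundary"`` — identical formulations, then every test-arm
      concentration multiplied by ``boundary`` so the true GMR of both
      metrics sits exactly on a BE limit; the pass fraction estimates the
      type-I error of the assessment.
    * ``"custom"`` — the supplied ``delta`` shift vector.
    """
    if n_reps < 20:
        raise ValueError("need at least 20 replicates")
    rng = np.random.default_rng(rng)
    if placement in ("null", "boundary"):
        pop_run = pop.with_delta((1.0,) * 6)
    elif placement == "custom":
        if delta is None:
            raise ValueError("custom placement requires a delta vector")
        pop_run = pop.with_delta(delta)
    else:
        raise ValueError(f"unknown placement {placement!r}")

    passes = 0
    for _ in range(n_reps):
        data = simulate_trial_scaled(
            design, pop_run, rng,
            test_scale=boundary if placement == "boundary" else 1.0)
        res = be_decision_workflow_A(data, design.analysis_interval,
                                     alpha=alpha, limits=limits)
        passes += res.passed
    p = passes / n_reps
    se = float(np.sqrt(p * (1.0 - p) / n_reps))
    return PowerResult(pass_fraction=float(p), mc_se=se, n_reps=n_reps,
                       placement=placement)


def simulate_trial_scaled(design: TrialDesign, pop: pm.PopulationParams,
                          rng, test_scale: float = 1.0) -> ConcentrationDataset:
    """One trial with every test-arm concentration multiplied by
    ``test_scale`` (a pure shift of the true GMR; NCA metrics scale the
    same way)."""
    data = ts.simulate_trial(design, pop, rng, keep_true_params=False)
    if test_scale != 1.0:
        mask = data.data["arm"] == pm.TEST
        data.data.loc[mask, "conc_ng_per_ml"] *= test_scale
    return data


# ---------------------------------------------------------------------------
# sensitivity ranking
# ---------------------------------------------------------------------------

def sensitivity_ranking(pop: pm.PopulationParams, regimen=None,
                        interval: tuple = ts.ANALYSIS_INTERVAL,
                        perturbation: float = 0.05) -> pd.DataFrame:
    """Local influence of each shift component on typical-subject exposure.

    Each of the six delta components in turn is set to
    ``1 + perturbation`` (others at 1) and the reference population's mean
    subject re-simulated; rows are sorted by influence (mean absolute
    percent change of Cmax and partial AUC).
    """
    if perturbation <= 0:
        raise ValueError("perturbation must be positive")
    if regimen is None:
        regimen = ts.standard_regimen()
    base_pop = pop.with_delta((1.0,) * 6)
    base = spk.exposure_model_integrated(
        pm.mean_subject(base_pop, pm.REFERENCE), regimen, interval)
    rows = []
    for i, name in enumerate(pm.DELTA_ORDER):
        delta = [1.0] * 6
        delta[i] = 1.0 + perturbation
        subj = pm.mean_subject(base_pop.with_delta(delta), pm.TEST)
        m = spk.exposure_model_integrated(subj, regimen, interval)
        dc = 100.0 * (m.cmax / base.cmax - 1.0)
        da = 100.0 * (m.auc / base.auc - 1.0)
        rows.append((name, i + 1, dc, da, 0.5 * (abs(dc) + abs(da))))
    out = pd.DataFrame(rows, columns=["parameter", "delta_index",
                                      "pct_change_cmax", "pct_change_auc",
                                      "influence"])
    out = out.sort_values("influence", ascending=False,
                          ignore_index=True)
    out["rank"] = np.arange(1, 7)
    return out


# ---------------------------------------------------------------------------
# safe space
# ---------------------------------------------------------------------------

@dataclass
class SafeSpaceMap:
    """Evaluated shift points with per-point GMRs and decisions.

    ``mode`` is ``"A_fuzzy"`` (full-trial TOST verdicts, blurred by trial
    noise) or ``"B_crisp"`` (averaged model-integrated ratios).
    """

    table: pd.DataFrame
    mode: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def safe_space_A(pop: pm.PopulationParams, design: TrialDesign,
                 n_trials: int,
                 rng: np.random.Generator | int | None = None,
                 delta_low: float = 0.5, delta_high: float = 2.0,
                 alpha: float = 0.05,
                 limits: tuple[float, float] = BE_LIMITS) -> SafeSpaceMap:
    """Fuzzy map: each trial draws delta ~ U[low, high]^6, runs a full
    noisy trial and records the workflow-A verdict."""
    if n_trials < 10:
        raise ValueError("need at least 10 trials")
    rng = np.random.default_rng(rng)
    rows = []
    for _ in range(n_trials):
        delta = rng.uniform(delta_low, delta_high, size=6)
        try:
            data = ts.simulate_trial(design, pop.with_delta(delta), rng,
                                     keep_true_params=False)
            res = be_decision_workflow_A(data, design.analysis_interval,
                                         alpha=alpha, limits=limits)
        except (ValueError, VbeError):
            continue  # keep mapping the remaining points
        rows.append((*delta, res.cmax.gmr, res.auc.gmr, res.passed))
    cols = [f"delta{i + 1}" for i in range(6)] + ["gmr_cmax", "gmr_auc",
                                                  "pass"]
    return SafeSpaceMap(table=pd.DataFrame(rows, columns=cols), mode="A_fuzzy")


def safe_space_B(pop: pm.PopulationParams, grid: Sequence[tuple[float, float]],
                 n_trials: int, n_per_arm: int,
                 rng: np.random.Generator | int | None = None,
                 regimen=None, interval: tuple = ts.ANALYSIS_INTERVAL,
                 limits: tuple[float, float] = BE_LIMITS,
                 rule: str = "mean", threshold: float = 0.95,
                 dt_max: float = 1.0) -> SafeSpaceMap:
    """Crisp map over a (delta1, delta2) grid.

    At each grid point the shift is fixed (no posterior uncertainty) and
    ``n_trials`` virtual trials of ``n_per_arm`` subjects are simulated.
    Under the default ``rule="mean"`` a point is in the safe space iff the
    averaged dCmax and dAUC both lie inside the limits; ``rule="prob"``
    instead applies the workflow-B probability criterion at the point.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    rng = np.random.default_rng(rng)
    if regimen is None:
        regimen = ts.standard_regimen()
    lo, hi = limits
    rows = []
    for d1, d2 in grid:
        popd = pop.with_delta((d1, d2, 1.0, 1.0, 1.0, 1.0))
        dc = np.empty(n_trials)
        da = np.empty(n_trials)
        for t in range(n_trials):
            dc[t], da[t] = _trial_ratio(popd, regimen, interval, n_per_arm,
                                        rng, dt_max=dt_max)
        if rule == "mean":
            mc, ma = np.exp(np.log(dc).mean()), np.exp(np.log(da).mean())
            ok = bool(lo <= mc <= hi and lo <= ma <= hi)
        elif rule == "prob":
            p = float(((dc >= lo) & (dc <= hi) & (da >= lo)
                       & (da <= hi)).mean())
            mc, ma = np.exp(np.log(dc).mean()), np.exp(np.log(da).mean())
            ok = p >= threshold
        else:
            raise ValueError(f"unknown rule {rule!r}")
        rows.append((d1, d2, mc, ma, ok))
    table = pd.DataFrame(rows, columns=["delta1", "delta2", "gmr_cmax",
                                        "gmr_auc", "in_safe_space"])
    return SafeSpaceMap(table=table, mode="B_crisp")


def refine_boundary_delta2(pop: pm.PopulationParams, delta1: float,
                           lo: float, hi: float, n_trials: int,
                           n_per_arm: int,
                           rng: np.random.Generator | int | None = None,
                           tol: float = 0.01, limits=BE_LIMITS,
                           **kwargs) -> float:
    """Bisect the workflow-B safe-space boundary along delta2 at a fixed
    delta1.  ``lo`` must be inside the safe space and ``hi`` outside."""
    rng = np.random.default_rng(rng)

    def inside(d2: float) -> bool:
        m = safe_space_B(pop, [(delta1, d2)], n_trials, n_per_arm, rng,
                         limits=limits, **kwargs)
        return bool(m.table["in_safe_space"].iloc[0])

    if not inside(lo) or inside(hi):
        raise ValueError("bisection bracket does not straddle the boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if inside(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
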