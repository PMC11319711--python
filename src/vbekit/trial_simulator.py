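"""Virtual parallel bioequivalence trials.

A trial draws virtual subjects per arm from the population model, solves
their concentration profiles, and applies the lognormal residual
measurement model

    C_obs(t) = C_model(t) * exp(sigma * eps),   eps ~ N(0, 1)

so observed concentrations are strictly positive.  The module also provides
non-compartmental (NCA) exposure metrics, trial summaries, predictive-check
percentile bands, and lossless CSV round-tripping.  It doubles as the
synthetic-data generator: the shipped abbreviated design (25 subjects/arm,
four monthly 150 mg eq. PP1M injections followed by four 3-monthly
525 mg eq. PP3M injections, five sampling weeks) emulates the abbreviated
trial that feeds model recalibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import population_model as pm
from . import structural_pk as spk
from .exceptions import InsufficientDataError
from .structural_pk import DosingRegimen, ExposureMetrics, PP1M, PP3M

WEEK = 7.0

#: sampling weeks printed for the recalibration dataset
SCHEDULE_WEEKS_54_63 = tuple(w * WEEK for w in (54, 55, 57, 59, 63))
#: alternative printed schedule used for the exposure summaries
SCHEDULE_WEEKS_54_65 = tuple(w * WEEK for w in (54, 55, 57, 61, 65))
SCHEDULES = {
    "weeks_54_63": SCHEDULE_WEEKS_54_63,
    "weeks_54_65": SCHEDULE_WEEKS_54_65,
}

#: last dosing period analysed: 11 weeks from the final injection at week 54
ANALYSIS_INTERVAL = (54 * WEEK, 65 * WEEK)

DATA_COLUMNS = ("subject", "arm", "time_days", "conc_ng_per_ml")


def standard_regimen(pp1m_dose: float = 150.0,
                     pp3m_dose: float = 525.0) -> DosingRegimen:
    """Run-in of four monthly PP1M injections, then four 3-monthly PP3M
    injections; the final injection opens the analysed dosing period."""
    events = [(28.0 * j, pp1m_dose, PP1M) for j in range(4)]
    events += [((15 + 13 * j) * WEEK, pp3m_dose, PP3M) for j in range(4)]
    return DosingRegimen.from_events(events, horizon=65 * WEEK)


@dataclass(frozen=True)
class TrialDesign:
    """Arm sizes, regimen, sampling schedule and analysis window."""

    n_per_arm: int
    regimen: DosingRegimen
    sampling_times: tuple[float, ...]
    analysis_interval: tuple[float, float] = ANALYSIS_INTERVAL
    dt_max: float = 0.5

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("need at least 2 subjects per arm")
        st = np.asarray(self.sampling_times)
        if st.size < 1 or np.any(np.diff(st) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        t0, t1 = self.analysis_interval
        if not t0 < t1:
            raise ValueError("analysis interval must be non-empty")
        if (self.regimen.horizon is not None
                and st[-1] > self.regimen.horizon + 1e-9):
            raise ValueError("sampling times exceed the regimen horizon")


def abbreviated_design(n_per_arm: int = 25,
                       schedule: str = "weeks_54_63") -> TrialDesign:
    return TrialDesign(n_per_arm=n_per_arm, regimen=standard_regimen(),
                       sampling_times=SCHEDULES[schedule])


def large_design(n_per_arm: int = 130,
                 schedule: str = "weeks_54_63") -> TrialDesign:
    return TrialDesign(n_per_arm=n_per_arm, regimen=standard_regimen(),
                       sampling_times=SCHEDULES[schedule])


@dataclass
class ConcentrationDataset:
    """Long-format measured concentrations with optional true parameters.

    ``data`` columns: subject, arm, time_days, conc_ng_per_ml.  When the
    dataset was simulated, ``true_params`` carries one row per subject with
    the generating :data:`vbekit.structural_pk.THETA_FIELDS`.
    """

    data: pd.DataFrame
    true_params: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = set(DATA_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset is missing columns {sorted(missing)}")
        if (self.data["conc_ng_per_ml"] <= 0).any():
            raise ValueError("concentrations must be strictly positive")
        if self.data.duplicated(["subject", "time_days"]).any():
            raise ValueError("duplicate (subject, time) records")

    def arm(self, arm: str) -> pd.DataFrame:
        return self.data[self.data["arm"] == arm]

    @property
    def n_records(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path,
               params_path: str | Path | None = None) -> None:
        self.data.to_csv(path, index=False)
        if params_path is not None and self.true_params is not None:
            self.true_params.to_csv(params_path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path,
                 params_path: str | Path | None = None) -> "ConcentrationDataset":
        data = pd.read_csv(path)
        params = pd.read_csv(params_path) if params_path else None
        return cls(data=data, true_params=params)


def simulate_trial(design: TrialDesign, pop: pm.PopulationParams,
                   rng: np.random.Generator | int | None = None,
                   keep_true_params: bool = True) -> ConcentrationDataset:
    """Simulate one two-arm parallel trial.

    Reference-arm subjects are drawn from the configured population;
    test-arm subjects from the delta-shifted population.  Measured values
    add the lognormal residual error (``pop.resid_sd_log``); a zero
    residual SD returns noise-free model predictions.
    """
    rng = np.random.default_rng(rng)
    times = np.asarray(design.sampling_times)
    frames, params = [], []
    for arm, prefix in ((pm.REFERENCE, "R"), (pm.TEST, "T")):
        theta = pm.sample_arm(pop, arm, design.n_per_arm, rng)
        conc = spk.simulate_population(theta, design.regimen, pop.tl1, times,
                                       dt_max=design.dt_max)
        if pop.resid_sd_log > 0:
            conc = conc * np.exp(pop.resid_sd_log *
                                 rng.standard_normal(conc.shape))
        ids = [f"{prefix}{i + 1:03d}" for i in range(design.n_per_arm)]
        frames.append(pd.DataFrame({
            "subject": np.repeat(ids, times.size),
            "arm": arm,
            "time_days": np.tile(times, design.n_per_arm),
            "conc_ng_per_ml": conc.ravel(),
        }))
        if keep_true_params:
            df = pd.DataFrame(theta, columns=list(spk.THETA_FIELDS))
            df.insert(0, "subject", ids)
            df.insert(1, "arm", arm)
            params.append(df)
    return ConcentrationDataset(
        data=pd.concat(frames, ignore_index=True),
        true_params=pd.concat(params, ignore_index=True) if params else None)


# ---------------------------------------------------------------------------
# non-compartmental analysis
# ---------------------------------------------------------------------------

def nca_metrics(times: Sequence[float], concs: Sequence[float],
                interval: tuple[float, float]) -> ExposureMetrics:
    """Observed Cmax and linear-trapezoid AUC within ``interval``."""
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    order = np.argsort(times)
    times, concs = times[order], concs[order]
    t0, t1 = interval
    mask = (times >= t0 - 1e-9) & (times <= t1 + 1e-9)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"need >= 2 observations in [{t0}, {t1}], got {int(mask.sum())}")
    t, c = times[mask], concs[mask]
    return ExposureMetrics(cmax=float(c.max()),
                           auc=float(np.trapezoid(c, t)),
                           interval=(float(t0), float(t1)), method="nca")


def nca_table(dataset: ConcentrationDataset,
              interval: tuple[float, float] = ANALYSIS_INTERVAL) -> pd.DataFrame:
    """Per-subject NCA metrics: columns subject, arm, cmax, auc."""
    rows = []
    for (subject, arm), grp in dataset.data.groupby(["subject", "arm"],
                                                    sort=True):
        try:
            m = nca_metrics(grp["time_days"], grp["conc_ng_per_ml"], interval)
        except InsufficientDataError as err:
            raise InsufficientDataError(f"subject {subject}: {err}") from err
        rows.append((subject, arm, m.cmax, m.auc))
    return pd.DataFrame(rows, columns=["subject", "arm", "cmax", "auc"])


def geometric_mean(x) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(x))))


def geometric_cv(x) -> float:
    """Natural-space CV derived from the log-variance: sqrt(exp(s^2) - 1)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("CV requires strictly positive values")
    s2 = np.var(np.log(x), ddof=1)
    return float(np.sqrt(np.expm1(s2)))


def summarize_trial(metrics: pd.DataFrame) -> dict:
    """Arm geometric means, CVs and test/reference GMRs for cmax and auc.

    ``metrics`` is the output of :func:`nca_table` (or any frame with
    subject/arm/cmax/auc columns).
    """
    out: dict = {}
    for arm in pm.ARMS:
        sub = metrics[metrics["arm"] == arm]
        if sub.empty:
            raise ValueError(f"arm {arm!r} has no subjects")
        out[arm] = {m: {"gm": geometric_mean(sub[m]),
                        "cv": geometric_cv(sub[m])}
                    for m in ("cmax", "auc")}
    out["gmr"] = {m: out[pm.TEST][m]["gm"] / out[pm.REFERENCE][m]["gm"]
                  for m in ("cmax", "auc")}
    return out


# ---------------------------------------------------------------------------
# predictive checking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictiveBands:
    """Envelope of within-trial concentration percentiles across trials.

    ``bands[i, j, :]`` holds the (lower, upper) envelope bounds of summary
    ``j`` (median, 5th, 95th within-trial percentile) at ``times[i]``.
    """

    times: np.ndarray
    bands: np.ndarray  # (n_times, 3, 2)
    summaries: tuple[str, ...] = ("median", "p5", "p95")
    envelope: tuple[float, float] = (5.0, 95.0)

    def to_frame(self) -> pd.DataFrame:
        rows = {"time_days": self.times}
        for j, s in enumerate(self.summaries):
            rows[f"{s}_lo"] = self.bands[:, j, 0]
            rows[f"{s}_hi"] = self.bands[:, j, 1]
        return pd.DataFrame(rows)


def predictive_check_bands(pop: pm.PopulationParams, design: TrialDesign,
                           n_trials: int,
                           rng: np.random.Generator | int | None = None,
                           times: Sequence[float] | None = None,
                           arm: str = pm.REFERENCE) -> PredictiveBands:
    """Simulate ``n_trials`` single-arm cohorts and summarise them.

    For each trial the within-trial median and 5th/95th percentile of the
    measured concentration are computed at every time; the band reported
    for each of the three summaries is its 5th-95th percentile envelope
    across trials.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(rng)
    if times is None:
        times = np.arange(1.0, design.regimen.horizon or 455.0 + 1e-9, WEEK)
    times = np.asarray(times, dtype=float)
    per_trial = np.empty((n_trials, 3, times.size))
    for t in range(n_trials):
        theta = pm.sample_arm(pop, arm, design.n_per_arm, rng)
        conc = spk.simulate_population(theta, design.regimen, pop.tl1, times,
                                       dt_max=design.dt_max)
        if pop.resid_sd_log > 0:
            conc = conc * np.exp(pop.resid_sd_log *
                                 rng.standard_normal(conc.shape))
        per_trial[t, 0] = np.median(conc, axis=0)
        per_trial[t, 1] = np.percentile(conc, 5, axis=0)
        per_trial[t, 2] = np.percentile(conc, 95, axis=0)
    lo = np.percentile(per_trial, 5, axis=0)
    hi = np.percentile(per_trial, 95, axis=0)
    bands = np.stack([lo, hi], axis=-1).transpose(1, 0, 2)
    return PredictiveBands(times=times, bands=bands)
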