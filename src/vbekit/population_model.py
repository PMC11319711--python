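"""Hierarchical population layer.

Virtual subjects are drawn around population geometric means with lognormal
inter-individual variability (zero random-effect covariances; only the
variances are used).  The dose fractions ``f1`` and ``f3`` are handled
through a positive latent variable kappa that is itself lognormal; two
back-transform dialects are provided because the two published transform
equations do not compose consistently:

* ``paper_logistic`` (default): theta = 1 / (1 + exp(-kappa)).  Since kappa
  is positive, fractions are confined to (0.5, 1).
* ``odds_ratio``: theta = kappa / (1 + kappa), the self-consistent odds
  reading, under which the kappa geometric mean mu/(1-mu) maps back to the
  population mean fraction mu.

Test and reference formulations differ only through ``delta``, a vector of
six multiplicative shifts applied to the population locations of the
drug-release parameters, in the order

    (f3, kas3_max, kar3_max, kas3_50, kar3_50, gamma)

(for ``f3`` the shift acts on the latent kappa location).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .structural_pk import THETA_FIELDS, SubjectParams

#: subject-varying lognormal parameters (geometric means in ``mu``)
VARYING = ("ka1", "kar3_50", "kas3_max", "kas3_50", "CL", "V")
#: fraction parameters handled on the latent kappa scale
FRACTIONS = ("f1", "f3")
#: parameters shared by all subjects
SHARED = ("kar3_max", "gamma")
#: order of the formulation-shift vector delta
DELTA_ORDER = ("f3", "kas3_max", "kar3_max", "kas3_50", "kar3_50", "gamma")

TRANSFORMS = ("paper_logistic", "odds_ratio")

REFERENCE = "reference"
TEST = "test"
ARMS = (REFERENCE, TEST)


def fraction_transform(kappa, dialect: str = "paper_logistic"):
    """Map a positive latent kappa to a fraction in (0, 1)."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be strictly positive")
    if dialect == "paper_logistic":
        out = 1.0 / (1.0 + np.exp(-kappa))
    elif dialect == "odds_ratio":
        out = kappa / (1.0 + kappa)
    else:
        raise ValueError(f"unknown transform dialect {dialect!r}")
    return out if out.ndim else float(out)


def fraction_inverse(theta, dialect: str = "paper_logistic"):
    """Inverse of :func:`fraction_transform`; domain error outside (0, 1)."""
    theta = np.asarray(theta, dtype=float)
    if np.any((theta <= 0.0) | (theta >= 1.0)):
        raise ValueError("fractions must lie strictly inside (0, 1)")
    if dialect == "paper_logistic":
        if np.any(theta <= 0.5):
            raise ValueError(
                "paper_logistic fractions must exceed 0.5 (kappa > 0)")
        out = -np.log(1.0 / theta - 1.0)
    elif dialect == "odds_ratio":
        out = theta / (1.0 - theta)
    else:
        raise ValueError(f"unknown transform dialect {dialect!r}")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PopulationParams:
    """Population distribution of the structural PK parameters.

    Parameters
    ----------
    mu
        Geometric means of the subject-varying lognormal parameters
        (:data:`VARYING`).
    frac_mean
        Population mean fractions for ``f1`` and ``f3``; the latent kappa
        location is the corresponding odds ``mu / (1 - mu)``.
    shared
        Values of ``kar3_max`` and ``gamma``, identical for all subjects.
    sigma_log
        Log-space SDs for every subject-varying parameter (for fractions:
        SD of log kappa).  Zero is allowed and collapses the distribution.
    qc0_gm, qc0_gsd
        Geometric mean / geometric SD of the time-zero central-compartment
        amount (mg eq.).
    resid_sd_log
        Residual measurement error SD in log space (sigma of the lognormal
        concentration error).
    delta
        Six multiplicative test/reference shifts in :data:`DELTA_ORDER`.
    tl1
        Zero-order release-window length (days), a structural constant.
    """

    mu: Mapping[str, float]
    frac_mean: Mapping[str, float]
    shared: Mapping[str, float]
    sigma_log: Mapping[str, float]
    qc0_gm: float
    qc0_gsd: float
    resid_sd_log: float
    delta: tuple[float, ...] = (1.0,) * 6
    transform: str = "paper_logistic"
    tl1: float = 2.0

    def __post_init__(self) -> None:
        for p in VARYING:
            if not self.mu.get(p, 0.0) > 0:
                raise ValueError(f"geometric mean for {p} must be positive")
        for p in FRACTIONS:
            v = self.frac_mean.get(p)
            if v is None or not 0.0 < v < 1.0:
                raise ValueError(f"population mean fraction {p} must be in (0,1)")
        for p in SHARED:
            if not self.shared.get(p, 0.0) > 0:
                raise ValueError(f"shared value for {p} must be positive")
        for p in VARYING + FRACTIONS:
            if self.sigma_log.get(p, 0.0) < 0:
                raise ValueError(f"sigma_log[{p}] must be >= 0")
        if self.qc0_gm <= 0 or self.qc0_gsd < 1.0:
            raise ValueError("Qc0 geometric mean must be > 0 and GSD >= 1")
        if self.resid_sd_log < 0:
            raise ValueError("residual log-SD must be >= 0")
        if len(self.delta) != 6 or any(d <= 0 for d in self.delta):
            raise ValueError("delta must be six strictly positive components")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform dialect {self.transform!r}")
        if self.tl1 <= 0:
            raise ValueError("tl1 must be positive")

    def with_delta(self, delta) -> "PopulationParams":
        return replace(self, delta=tuple(float(d) for d in delta))

    def kappa_location(self, name: str) -> float:
        """Latent kappa geometric mean (odds of the population mean fraction)."""
        m = self.frac_mean[name]
        return m / (1.0 - m)

    def reference_locations(self) -> dict[str, float]:
        """Population locations of the six shiftable drug-release parameters."""
        return {
            "f3": self.kappa_location("f3"),
            "kas3_max": self.mu["kas3_max"],
            "kar3_max": self.shared["kar3_max"],
            "kas3_50": self.mu["kas3_50"],
            "kar3_50": self.mu["kar3_50"],
            "gamma": self.shared["gamma"],
        }


def apply_formulation_shift(locations: Mapping[str, float],
                            delta) -> dict[str, float]:
    """Multiply the six drug-release locations by their delta components.

    ``locations`` must carry the keys of :data:`DELTA_ORDER` (the ``f3``
    entry is its latent kappa location); any further keys pass through
    unchanged.
    """
    delta = np.asarray(delta, dtype=float)
    if delta.shape != (6,):
        raise ValueError("delta must have exactly six components")
    if np.any(delta <= 0):
        raise ValueError("delta components must be strictly positive")
    out = dict(locations)
    for name, d in zip(DELTA_ORDER, delta):
        if name not in out:
            raise KeyError(f"locations is missing {name!r}")
        out[name] = out[name] * float(d)
    if not out["f3"] > 0:
        raise ValueError("shifted f3 latent location must stay positive")
    return out


def arm_locations(pop: PopulationParams, arm: str) -> dict[str, float]:
    """Effective population locations for one trial arm.

    The reference arm uses the configured locations; the test arm applies
    the formulation-shift vector ``pop.delta``.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    loc = {
        **{p: pop.mu[p] for p in VARYING},
        "f1": pop.kappa_location("f1"),
        "f3": pop.kappa_location("f3"),
        "kar3_max": pop.shared["kar3_max"],
        "gamma": pop.shared["gamma"],
    }
    if arm == TEST:
        shifted = apply_formulation_shift(
            {k: loc[k] for k in DELTA_ORDER}, pop.delta)
        loc.update(shifted)
    return loc


def sample_arm(pop: PopulationParams, arm: str, n: int,
               rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` subjects for one arm as a (n, 11) theta matrix.

    Columns follow :data:`vbekit.structural_pk.THETA_FIELDS`.  The draw
    order is fixed (parameter by parameter) so a seeded generator yields
    reproducible cohorts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    loc = arm_locations(pop, arm)
    cols: dict[str, np.ndarray] = {}
    for p in FRACTIONS:
        s = pop.sigma_log.get(p, 0.0)
        kappa = loc[p] * np.exp(s * rng.standard_normal(n))
        cols[p] = fraction_transform(kappa, pop.transform)
    for p in VARYING:
        s = pop.sigma_log.get(p, 0.0)
        cols[p] = loc[p] * np.exp(s * rng.standard_normal(n))
    for p in SHARED:
        cols[p] = np.full(n, loc[p])
    cols["Qc0"] = pop.qc0_gm * np.exp(np.log(pop.qc0_gsd) *
                                      rng.standard_normal(n))
    return np.column_stack([cols[f] for f in THETA_FIELDS])


def sample_subject(pop: PopulationParams, arm: str,
                   rng: np.random.Generator) -> SubjectParams:
    """Draw a single virtual subject (see :func:`sample_arm`)."""
    row = sample_arm(pop, arm, 1, rng)[0]
    kw = dict(zip(THETA_FIELDS, row))
    return SubjectParams(tl1=pop.tl1, **kw)


def mean_subject(pop: PopulationParams, arm: str) -> SubjectParams:
    """The deterministic 'typical' subject: all random effects at their
    location, Qc0 at its geometric mean."""
    loc = arm_locations(pop, arm)
    kw = {p: loc[p] for p in VARYING + SHARED}
    kw["f1"] = fraction_transform(loc["f1"], pop.transform)
    kw["f3"] = fraction_transform(loc["f3"], pop.transform)
    return SubjectParams(tl1=pop.tl1, Qc0=pop.qc0_gm, **kw)
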