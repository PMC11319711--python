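"""Run configuration: profile loading, validation and provenance.

A run configuration is a flat YAML document with sections for the
structural constants, population distribution, trial designs, MCMC
settings and the BE decision rule.  The shipped profile
``paliperidone-lai-v1`` carries documented placeholder values for the
paliperidone LAI case study.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import trial_simulator as ts
from .exceptions import ConfigurationError
from .population_model import PopulationParams

DEFAULT_PROFILE = "paliperidone-lai-v1"
_PROFILE_FILES = {DEFAULT_PROFILE: "paliperidone_lai.yaml"}


def _deep_update(base: dict, extra: Mapping) -> dict:
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            base[k] = _deep_update(base[k], v)
        else:
            base[k] = v
    return base


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with typed accessors."""

    raw: dict

    def __post_init__(self) -> None:
        for section in ("structural", "population", "designs", "mcmc",
                        "decision"):
            if section not in self.raw:
                raise ConfigurationError(f"missing config section {section!r}")
        lo, hi = self.raw["decision"]["limits"]
        if not lo < 1.0 < hi:
            raise ConfigurationError("BE limits must bracket 1")
        thr = self.raw["decision"]["threshold"]
        if not 0.0 < thr < 1.0:
            raise ConfigurationError("decision threshold must be in (0, 1)")

    # -- typed views --------------------------------------------------
    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def limits(self) -> tuple[float, float]:
        lo, hi = self.raw["decision"]["limits"]
        return float(lo), float(hi)

    @property
    def alpha(self) -> float:
        return float(self.raw["decision"]["alpha"])

    @property
    def threshold(self) -> float:
        return float(self.raw["decision"]["threshold"])

    def population(self, delta=None) -> PopulationParams:
        p = self.raw["population"]
        qc0 = p["qc0"]
        return PopulationParams(
            mu=dict(p["mu"]),
            frac_mean=dict(p["fraction_means"]),
            shared=dict(p["shared"]),
            sigma_log=dict(p["sigma_log"]),
            qc0_gm=float(qc0["geometric_mean"]),
            qc0_gsd=float(qc0["geometric_sd"]),
            resid_sd_log=float(p["residual_sd_log"]),
            delta=tuple(delta if delta is not None else p["delta"]),
            transform=p.get("transform", "paper_logistic"),
            tl1=float(self.raw["structural"]["tl1_days"]),
        )

    def design(self, name: str) -> ts.TrialDesign:
        designs = self.raw["designs"]
        if name not in designs:
            raise ConfigurationError(f"unknown trial design {name!r}; "
                                     f"available: {sorted(designs)}")
        d = designs[name]
        return ts.TrialDesign(
            n_per_arm=int(d["n_per_arm"]),
            regimen=ts.standard_regimen(),
            sampling_times=ts.SCHEDULES[d.get("schedule", "weeks_54_63")],
        )

    def mcmc_settings(self) -> dict:
        return dict(self.raw["mcmc"])

    # -- provenance ---------------------------------------------------
    def hash(self) -> str:
        """Stable SHA-256 of the canonical JSON form of the config."""
        blob = json.dumps(self.raw, sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()

    def manifest(self, seed: int, stage: str) -> dict:
        from . import __version__
        return {"stage": stage, "seed": int(seed),
                "config_hash": self.hash(),
                "profile": self.raw.get("profile", "custom"),
                "vbekit_version": __version__}


def load_profile(name: str = DEFAULT_PROFILE) -> RunConfig:
    """Load a profile shipped with the package."""
    if name not in _PROFILE_FILES:
        raise ConfigurationError(f"unknown profile {name!r}")
    text = resources.files("vbekit.profiles").joinpath(
        _PROFILE_FILES[name]).read_text()
    return RunConfig(yaml.safe_load(text))


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load a config file, filling gaps from the default profile.

    ``path=None`` returns the default profile; a user file only needs the
    keys it overrides.
    """
    base = load_profile().raw
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError("config file must map sections to values")
        base = _deep_update(base, user)
    if overrides:
        base = _deep_update(base, overrides)
    return RunConfig(base)
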