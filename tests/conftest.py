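import numpy as np
import pytest

from vbekit import load_profile
from vbekit import trial_simulator as ts
from vbekit.structural_pk import PP1M, PP3M, DosingRegimen, SubjectParams


@pytest.fixture(scope="session")
def cfg():
    return load_profile()


@pytest.fixture(scope="session")
def pop(cfg):
    """Shipped population profile with the abbreviated-trial shift
    (delta2 = 1.05)."""
    return cfg.population()


@pytest.fixture(scope="session")
def pop_null(cfg):
    """Identical test and reference formulations."""
    return cfg.population(delta=(1.0,) * 6)


@pytest.fixture(scope="session")
def regimen():
    return ts.standard_regimen()


@pytest.fixture(scope="session")
def subject(pop_null):
    """A deterministic mid-population subject."""
    from vbekit.population_model import mean_subject
    return mean_subject(pop_null, "reference")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240730)


def random_subject(rng, tl1=2.0):
    """A positive, physiologically plausible random subject."""
    e = rng.uniform
    return SubjectParams(
        f1=e(0.05, 0.9), tl1=tl1, ka1=e(0.005, 0.08),
        f3=e(0.05, 0.9), kar3_max=e(4, 30), kar3_50=e(20, 200),
        kas3_max=e(2, 12), kas3_50=e(50, 400), gamma=e(1.0, 2.5),
        CL=e(60, 300), V=e(150, 800), Qc0=e(0.0, 80))


def random_regimen(rng):
    """A random multi-injection schedule mixing both formulations."""
    n = int(rng.integers(1, 7))
    times = np.sort(rng.uniform(0, 350, size=n))
    times = np.concatenate([[0.0], times + 5.0])
    events = []
    for t in times:
        form = PP1M if rng.random() < 0.5 else PP3M
        events.append((float(t), float(rng.uniform(50, 600)), form))
    return DosingRegimen.from_events(events)
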