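import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from apmscore.simulate import generate, paper_default_config, resolve_intercept


@pytest.fixture(scope="session")
def score_tables():
    from apmscore.severity import load_score_tables

    return load_score_tables()


@pytest.fixture(scope="session")
def resolved_default():
    """Paper-default config with the intercept calibrated once."""
    return resolve_intercept(paper_default_config())


@pytest.fixture(scope="session")
def cohort_10k(resolved_default):
    """A mid-size paper-default cohort for derivation/evaluation tests."""
    return generate(resolved_default.replace(n=10_000, seed=11)).data


@pytest.fixture(scope="session")
def cohort_100k(resolved_default):
    """A large paper-default cohort for calibration checks."""
    return generate(resolved_default.replace(n=100_000, seed=123)).data


def logistic_cohort(n, intercept, slope, seed, t_low=6, t_high=21):
    """Integer-thickness cohort with death ~ Bernoulli(expit(a + b*t))."""
    rng = np.random.default_rng(seed)
    t = rng.integers(t_low, t_high + 1, size=n).astype(float)
    p = 1.0 / (1.0 + np.exp(-(intercept + slope * t)))
    return pd.DataFrame({"apm_mm": t, "death": (rng.uniform(size=n) < p).astype(int)})
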