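"""Shared fixtures: small synthetic cohorts built at test time."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cvmipred import Cohort

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_bivariate_cohort(n=500, rho=0.6, missing_rate=0.3, seed=42):
    """Standard bivariate-normal predictors with MCAR missingness in x1 and
    an outcome independent of the predictors (so the conditional law of x1
    given everything else stays exactly normal)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    x2 = z[:, 0]
    x1 = rho * x2 + np.sqrt(1 - rho**2) * z[:, 1]
    y = (rng.random(n) < 0.5).astype(float)
    x1_masked = x1.copy()
    miss = rng.random(n) < missing_rate
    x1_masked[miss] = np.nan
    df = pd.DataFrame({"x1": x1_masked, "x2": x2, "y": y})
    cohort = Cohort(df, "y")
    return cohort, x1, miss, rho


@pytest.fixture
def bivariate_cohort():
    return make_bivariate_cohort()


@pytest.fixture
def mixed_cohort():
    """Continuous + binary + categorical predictors with scattered missing
    cells and a dependent binary outcome."""
    rng = np.random.default_rng(7)
    n = 200
    x1 = rng.standard_normal(n)
    x2 = (rng.random(n) < 0.4).astype(float)
    cat = rng.choice(["a", "b", "c"], size=n, p=[0.5, 0.3, 0.2])
    eta = -0.5 + 0.8 * x1 + 0.6 * x2 + np.where(cat == "b", 0.4, 0.0)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    x1[rng.random(n) < 0.15] = np.nan
    x2 = x2.astype(object)
    x2[rng.random(n) < 0.10] = np.nan
    cat = cat.astype(object)
    cat[rng.random(n) < 0.10] = np.nan
    df = pd.DataFrame({"x1": x1, "x2": x2, "cat": cat, "y": y})
    return Cohort(df, "y")


@pytest.fixture
def complete_cohort():
    """A missing-free cohort for the complete-data reduction oracles."""
    rng = np.random.default_rng(11)
    n = 150
    X = rng.standard_normal((n, 3))
    eta = -0.3 + X @ np.array([0.8, -0.5, 0.4])
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    df = pd.DataFrame(X, columns=["x1", "x2", "x3"])
    df["y"] = y
    return Cohort(df, "y")
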