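"""Shared fixtures: seeded synthetic cohorts and planted regression tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rtacc import CohortConfig, build_analysis_table, rtacc_table
from rtacc.simulate import generate_cohort_frames, generate_participants, simulate_outcomes


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(seed=42)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One full calibrated cohort (130 participants, 24 weeks)."""
    return generate_cohort_frames(default_config)


@pytest.fixture(scope="session")
def analysis_table(cohort):
    participants, log = cohort
    values = rtacc_table(log)
    return build_analysis_table(participants, values)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(seed=7, n_participants=12, n_weeks=4)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort_frames(small_config)


def make_planted_table(config: CohortConfig) -> pd.DataFrame:
    """Analysis table built directly from the planted model.

    Uses the true coupling as the RTACC column (no stream measurement
    error), so planted regression coefficients are the exact truth.
    """
    participants = generate_participants(config)
    participants = simulate_outcomes(participants, config)
    table = participants.rename(columns={"rho_true": "rtacc"}).copy()
    table["rbans_change"] = table["rbans_week24"] - table["rbans_baseline"]
    return table


def python_pearson(xs, ys) -> float:
    """Independent brute-force Pearson: explicit sum formula in pure Python."""
    n = len(xs)
    sx = sum(xs)
    sy = sum(ys)
    sxx = sum(x * x for x in xs)
    syy = sum(y * y for y in ys)
    sxy = sum(x * y for x, y in zip(xs, ys))
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den


def python_mad_flags(values, k=3.0, scale=1.4826):
    """Brute-force MAD rule with a sort-based median, in pure Python."""

    def median(v):
        v = sorted(v)
        m = len(v) // 2
        return v[m] if len(v) % 2 else 0.5 * (v[m - 1] + v[m])

    med = median(list(values))
    mad = median([abs(x - med) for x in values])
    if mad == 0:
        return [False] * len(values)
    return [abs(x - med) > k * scale * mad for x in values]
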