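"""Shared fixtures: small synthetic studies and hypothesis configuration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from survwalk import PlantedTruth, RunConfig, generate_cohort, simulate_study

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """One full synthetic study at the default (cohort-emulating) settings."""
    return simulate_study(seed=9011)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort (160 samples, 50 genes, 10 miRNAs)."""
    truth = PlantedTruth()
    mrna, mirna, clinical = generate_cohort(160, 50, 10, truth, seed=17)
    return mrna, mirna, clinical, truth


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def toy_clinical():
    """Ten samples with a mix of events, censoring and grades."""
    rng = np.random.default_rng(3)
    n = 10
    return pd.DataFrame(
        {
            "survival_days": rng.integers(40, 900, n),
            "event": rng.integers(0, 2, n),
            "grade": ["II", "III", "IV", "II", "III", "IV", "II", "III", "IV", "II"],
            "age": rng.integers(20, 70, n),
            "gender": ["M", "F"] * 5,
        },
        index=pd.Index([f"S{i:03d}" for i in range(1, n + 1)], name="sample_id"),
    )
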