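"""Shared fixtures: cohorts and rate tables reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import mdd_lifecourse as ml
from mdd_lifecourse.cohort import (
    BaselinePrevalenceCoefficients,
    HazardCoefficients,
    RECOVERY_BANDS,
    default_config,
    recovery_config,
)

#: Seed for the fixed-seed statistical checks; chosen once, up front.
CHECK_SEED = 20240613


@pytest.fixture(scope="session")
def default_cfg():
    """Realistic study conditions, 50k participants."""
    return default_config(50_000, seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_cfg):
    return ml.generate_cohort(default_cfg)


@pytest.fixture(scope="session")
def default_specs(default_cfg):
    return {s.name: s for s in default_cfg.factor_specs}


@pytest.fixture(scope="session")
def recovery_cfg():
    """Event-rich recovery conditions on the coarse band partition."""
    return recovery_config(50_000, seed=CHECK_SEED, bands=RECOVERY_BANDS)


@pytest.fixture(scope="session")
def recovery_cohort(recovery_cfg):
    return ml.generate_cohort(recovery_cfg)


@pytest.fixture(scope="session")
def flat_config():
    """Homogeneous two-state truth (no covariates), for closed-form checks."""
    bands = ml.AgeBands.five_year()
    nb = bands.n_bands
    return default_config(
        50_000,
        seed=7,
        factor_specs=(),
        missing_rate=0.0,
        followup_gap_range=(2.0, 4.0),
        incidence=HazardCoefficients(tuple(np.log(np.full(nb, 0.1)))),
        remittance=HazardCoefficients(tuple(np.log(np.full(nb, 0.3)))),
        baseline_prevalence=BaselinePrevalenceCoefficients(np.log(0.3 / 0.7)),
    )


def constant_rate_table(lam: float, mu: float, p18: float,
                        strata=ml.DEFAULT_STRATA) -> ml.RateTable:
    bands = ml.AgeBands.five_year()
    nb = bands.n_bands
    return ml.RateTable(
        bands,
        {s: np.full(nb, lam) for s in strata},
        {s: np.full(nb, mu) for s in strata},
        {s: p18 for s in strata},
    )
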