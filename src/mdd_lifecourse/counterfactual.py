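"""Counterfactual rate tables: equalising mediator distributions.

A scenario replaces the low-education group's distribution of one or more
modifiable factors with the high-education group's, leaving everything
else (including the high-education stratum and the age-18 prevalence)
untouched, and rebuilds the transition rates by marginal standardisation
(g-computation-style averaging of model predictions over the modified
covariate rows).

Joint scenarios resample entire factor ROWS from the high-education group,
preserving the factors' mutual correlation, rather than resampling
independent marginals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import AgeBands
from .cohort import FactorSpec
from .exceptions import ConfigurationError
from .microsim import SimulationSettings, run_simulation
from .ratetable import EDUCATION_HIGH, EDUCATION_LOW, RateTable
from .rates import (
    INCIDENCE,
    REMITTANCE,
    TransitionModel,
    build_rate_table,
    fit_baseline_prevalence,
    fit_transition_model,
    impute_factors,
)


@dataclass(frozen=True)
class Scenario:
    """A named counterfactual: which factors are equalised across education."""

    name: str
    swapped_factors: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.swapped_factors:
            raise ConfigurationError(f"scenario {self.name!r}: swapped_factors is empty")


def swap_factor_rows(cohort: pd.DataFrame, factors, seed: int) -> pd.DataFrame:
    """Low-education rows get factor values resampled from high education.

    The swapped factors' values are drawn jointly (whole rows of those
    columns) from the high-education empirical distribution, with a fixed
    seed; all other covariates keep their observed low-education values.
    """
    factors = list(factors)
    absent = [f for f in factors if f not in cohort.columns]
    if absent:
        raise ConfigurationError(f"factors not present in cohort: {absent}")
    out = cohort.copy()
    low_idx = out.index[out["education_years"] == EDUCATION_LOW]
    high = out.loc[out["education_years"] == EDUCATION_HIGH, factors]
    if len(high) == 0 or len(low_idx) == 0:
        return out
    rng = np.random.default_rng(seed)
    donor = rng.integers(0, len(high), size=len(low_idx))
    out.loc[low_idx, factors] = high.to_numpy()[donor]
    return out


def counterfactual_rate_table(
    cohort: pd.DataFrame,
    models: tuple[TransitionModel, TransitionModel],
    baseline,
    bands: AgeBands,
    scenario: Scenario,
    seed: int = 0,
    method: str = "joint",
) -> RateTable:
    """Rate table under a counterfactual mediator distribution.

    ``models`` must include the scenario's factors as covariates (they were
    fitted on the observed cohort); the counterfactual enters purely through
    the covariate rows used for marginal standardisation.
    """
    for model in models:
        for f in scenario.swapped_factors:
            if not model.includes_factor(f):
                raise ConfigurationError(
                    f"scenario {scenario.name!r}: factor {f!r} is not a covariate of the "
                    f"{model.direction} model"
                )
    reference = swap_factor_rows(cohort, scenario.swapped_factors, seed)
    provenance = "counterfactual:" + "+".join(scenario.swapped_factors)
    return build_rate_table(models, baseline, bands, reference, method=method,
                            provenance=provenance)


@dataclass
class ScenarioOutput:
    scenario: Scenario | None  # None for baseline
    rate_table: RateTable
    summaries: dict  # Stratum -> LifeCourseSummary


def run_scenarios(
    cohort: pd.DataFrame,
    scenarios,
    settings: SimulationSettings,
    factor_specs: dict[str, FactorSpec] | None = None,
    bands: AgeBands | None = None,
    stratified: bool = True,
    method: str = "joint",
    impute_seed: int = 0,
    swap_seed: int = 0,
) -> dict[str, ScenarioOutput]:
    """Baseline plus counterfactual simulations under shared seeds.

    Transition models are fitted once, with the union of all swapped
    factors as covariates; every scenario's table is then simulated with
    the same :class:`SimulationSettings` so scenario contrasts share the
    Monte Carlo noise.  The returned mapping always contains ``"baseline"``.
    """
    from .stats import summarize  # local import to avoid a cycle

    bands = bands or AgeBands.five_year()
    scenarios = list(scenarios)
    all_factors: list[str] = []
    for sc in scenarios:
        for f in sc.swapped_factors:
            if f not in all_factors:
                all_factors.append(f)
    factor_names = [c for c in cohort.columns if c not in
                    ("id", "sex", "education_years", "age_baseline",
                     "mdd_baseline", "followup_gap", "mdd_followup")]
    cohort = impute_factors(cohort, factor_names, seed=impute_seed, factor_specs=factor_specs)
    baseline_prev = fit_baseline_prevalence(cohort)
    inc = fit_transition_model(cohort, INCIDENCE, tuple(all_factors), factor_specs,
                               stratified, bands)
    rem = fit_transition_model(cohort, REMITTANCE, tuple(all_factors), factor_specs,
                               stratified, bands)
    models = (inc, rem)

    def simulate(table: RateTable) -> dict:
        courses = run_simulation(table, settings)
        return {stratum: summarize(slc) for stratum, slc in courses.items()}

    base_table = build_rate_table(models, baseline_prev, bands, cohort, method=method)
    out = {"baseline": ScenarioOutput(None, base_table, simulate(base_table))}
    for sc in scenarios:
        table = counterfactual_rate_table(
            cohort, models, baseline_prev, bands, sc, seed=swap_seed, method=method
        )
        out[sc.name] = ScenarioOutput(sc, table, simulate(table))
    return out


def standard_scenarios(top_factors) -> list[Scenario]:
    """One single-factor scenario per selected mediator plus the joint swap."""
    top = list(top_factors)
    scenarios = [Scenario(f, (f,)) for f in top]
    scenarios.append(Scenario("joint", tuple(top)))
    return scenarios
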