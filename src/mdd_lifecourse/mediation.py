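"""Screening modifiable factors by their mediation of the education effect.

The screen uses the difference-of-coefficients method on the log-odds
scale: the transition model is fitted pooled (with ``female`` and centred
``education_years`` terms) twice — without and with the candidate factor —
and the mediating percentage is the relative shrinkage of the education
coefficient,

    100 * (beta_total - beta_adjusted) / beta_total.

Screening runs on the incidence direction; the method is deliberately
simple since its only downstream use is ranking factors for the
counterfactual scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bands import AgeBands
from .cohort import FactorSpec
from .exceptions import ConfigurationError, UndefinedMediationError
from .rates import INCIDENCE, fit_transition_model

#: |education log-odds| below this is treated as no effect to mediate.
DEFAULT_NULL_TOLERANCE = 1e-8


@dataclass(frozen=True)
class MediationResult:
    factor: str
    direction: str
    beta_total: float      # education log-odds without the factor
    beta_adjusted: float   # education log-odds with the factor
    mediating_percentage: float  # 100 * (total - adjusted) / total


def _education_coefficient(cohort, direction, extra, factor_specs, bands) -> float:
    model = fit_transition_model(
        cohort, direction, extra_covariates=extra, factor_specs=factor_specs,
        stratified=False, bands=bands,
    )
    return float(model.coefficients["education_years"])


def mediating_percentage(
    cohort: pd.DataFrame,
    factor: str,
    direction: str = INCIDENCE,
    factor_specs: dict[str, FactorSpec] | None = None,
    bands: AgeBands | None = None,
    adjust_for=(),
    null_tolerance: float = DEFAULT_NULL_TOLERANCE,
) -> MediationResult:
    """Mediating percentage of ``factor`` for the education -> MDD transition.

    ``adjust_for`` lists covariates held in both models (defaults to none).
    Raises :class:`UndefinedMediationError` when the total education effect
    is within ``null_tolerance`` of zero.
    """
    if factor not in cohort.columns:
        raise ConfigurationError(f"factor {factor!r} not present in the cohort")
    bands = bands or AgeBands.five_year()
    base = tuple(adjust_for)
    beta_total = _education_coefficient(cohort, direction, base, factor_specs, bands)
    if abs(beta_total) <= null_tolerance:
        raise UndefinedMediationError(
            f"education effect on {direction} is ~0 (|{beta_total:.2e}| <= "
            f"{null_tolerance}); mediating percentage is undefined"
        )
    beta_adjusted = _education_coefficient(
        cohort, direction, base + (factor,), factor_specs, bands
    )
    pct = 100.0 * (beta_total - beta_adjusted) / beta_total
    return MediationResult(factor, direction, beta_total, beta_adjusted, float(pct))


def screen_factors(
    cohort: pd.DataFrame,
    factors,
    direction: str = INCIDENCE,
    factor_specs: dict[str, FactorSpec] | None = None,
    bands: AgeBands | None = None,
) -> list[MediationResult]:
    """Mediating percentage for every candidate factor, one at a time."""
    return [
        mediating_percentage(cohort, f, direction, factor_specs, bands) for f in factors
    ]


def select_top_factors(results, k: int = 3) -> list[str]:
    """The ``k`` strongest incidence-direction mediators.

    Ordered by decreasing mediating percentage; ties broken alphabetically.
    """
    if not results:
        raise ConfigurationError("results: must be non-empty")
    if k < 1:
        raise ConfigurationError("k: must be >= 1")
    pool = [r for r in results if r.direction == INCIDENCE]
    if k > len(pool):
        raise ConfigurationError(
            f"k: requested {k} factors but only {len(pool)} incidence results available"
        )
    ranked = sorted(pool, key=lambda r: (-r.mediating_percentage, r.factor))
    return [r.factor for r in ranked[:k]]


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                factor=r.factor, direction=r.direction, beta_total=r.beta_total,
                beta_adjusted=r.beta_adjusted, mediating_percentage=r.mediating_percentage,
            )
            for r in results
        ]
    )
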