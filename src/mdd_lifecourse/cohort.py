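"""Synthetic two-wave panel cohorts with known ground-truth MDD dynamics.

The generator emulates the structure of a prospective population cohort as
used to parameterise the life-course model: one baseline observation (sex,
years of education, age, current MDD status, nine modifiable psychosocial
and lifestyle factors) and one follow-up MDD status after an irregular gap
of a few years.  The underlying truth is a continuous-time two-state
process with proportional-hazards covariate effects on piecewise-constant
age-band rates, so every downstream estimator can be checked against known
parameters.

Follow-up states are produced by exact event-history simulation of that
process over each individual's gap (multiple transitions within the gap are
possible), mirroring how a real panel only observes interval-censored
states.  Missingness in the factor columns is MCAR.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .bands import AgeBands, END_AGE, START_AGE
from .exceptions import ConfigurationError
from .microsim import simulate_two_state
from .ratetable import (
    DEFAULT_STRATA,
    EDUCATION_HIGH,
    EDUCATION_LOW,
    RateTable,
    Stratum,
)

#: Education is entered in models as years centred at the midpoint of the
#: two compared levels (10 and 16 years), so intercepts refer to 13 years.
EDUCATION_CENTER = 13.0

FACTOR_ENCODING_ORDINAL = "ordinal"
FACTOR_ENCODING_ONEHOT = "onehot"


# --------------------------------------------------------------------------
# Configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorSpec:
    """Education-conditional distribution of one modifiable factor.

    ``levels`` are numeric codes (higher = less favourable); ``probs_low`` /
    ``probs_high`` are the level probabilities for the low- and
    high-education group.  ``encoding`` controls how the factor enters
    linear predictors: ``"ordinal"`` uses the code itself as one feature,
    ``"onehot"`` uses one indicator per non-reference level (used for
    smoking: never/former/current).
    """

    name: str
    levels: tuple[int, ...]
    probs_low: tuple[float, ...]
    probs_high: tuple[float, ...]
    encoding: str = FACTOR_ENCODING_ORDINAL

    def __post_init__(self) -> None:
        for fld in ("probs_low", "probs_high"):
            p = np.asarray(getattr(self, fld), dtype=float)
            if p.shape != (len(self.levels),):
                raise ConfigurationError(f"{self.name}.{fld}: length mismatch with levels")
            if np.any(p < 0) or np.any(p > 1):
                raise ConfigurationError(f"{self.name}.{fld}: probabilities outside [0, 1]")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{self.name}.{fld}: probabilities must sum to 1")
        if self.encoding not in (FACTOR_ENCODING_ORDINAL, FACTOR_ENCODING_ONEHOT):
            raise ConfigurationError(f"{self.name}.encoding: unknown encoding {self.encoding!r}")

    def probs(self, education_years: int) -> np.ndarray:
        return np.asarray(
            self.probs_low if education_years == EDUCATION_LOW else self.probs_high, dtype=float
        )

    @property
    def feature_names(self) -> list[str]:
        if self.encoding == FACTOR_ENCODING_ORDINAL:
            return [self.name]
        return [f"{self.name}_{lvl}" for lvl in self.levels[1:]]

    def features_of_level(self, level) -> np.ndarray:
        """Feature row(s) for code(s) ``level``; shape (..., n_features)."""
        x = np.asarray(level, dtype=float)
        if self.encoding == FACTOR_ENCODING_ORDINAL:
            return x[..., None]
        return np.stack([(x == lvl).astype(float) for lvl in self.levels[1:]], axis=-1)


@dataclass(frozen=True)
class HazardCoefficients:
    """Ground-truth log-hazard model for one transition direction.

    hazard = exp(band_log_rates[band] + female * I(female)
                 + education_per_year * (education_years - 13)
                 + sum_k factors[k] * feature_k).
    """

    band_log_rates: tuple[float, ...]
    female: float = 0.0
    education_per_year: float = 0.0
    factors: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class BaselinePrevalenceCoefficients:
    """Logistic model for MDD status at the baseline interview.

    logit p = intercept + female * I(female)
              + education_per_year * (education_years - 13)
              + age_per_year * (age - 18).
    """

    intercept: float
    female: float = 0.0
    education_per_year: float = 0.0
    age_per_year: float = 0.0

    def probability(self, female, education_years, age) -> np.ndarray:
        lp = (
            self.intercept
            + self.female * np.asarray(female, dtype=float)
            + self.education_per_year * (np.asarray(education_years, dtype=float) - EDUCATION_CENTER)
            + self.age_per_year * (np.asarray(age, dtype=float) - START_AGE)
        )
        return 1.0 / (1.0 + np.exp(-lp))


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to draw a synthetic two-wave panel cohort."""

    n_individuals: int
    seed: int
    p_female: float = 0.5
    p_low_education: float = 0.5
    education_years_levels: tuple[int, int] = (EDUCATION_LOW, EDUCATION_HIGH)
    baseline_age_range: tuple[float, float] = (START_AGE, END_AGE)
    followup_gap_range: tuple[float, float] = (2.0, 5.0)
    factor_specs: tuple[FactorSpec, ...] = ()
    incidence: HazardCoefficients = None  # type: ignore[assignment]
    remittance: HazardCoefficients = None  # type: ignore[assignment]
    baseline_prevalence: BaselinePrevalenceCoefficients = None  # type: ignore[assignment]
    missing_rate: float = 0.0
    bands: AgeBands = field(default_factory=AgeBands.five_year)

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ConfigurationError("n_individuals: must be >= 0")
        for fld in ("p_female", "p_low_education", "missing_rate"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{fld}: probability outside [0, 1]")
        if tuple(self.education_years_levels) != (EDUCATION_LOW, EDUCATION_HIGH):
            raise ConfigurationError(
                f"education_years_levels: must be exactly ({EDUCATION_LOW}, {EDUCATION_HIGH})"
            )
        lo, hi = self.baseline_age_range
        if not (START_AGE <= lo < hi <= END_AGE):
            raise ConfigurationError("baseline_age_range: must satisfy 18 <= lo < hi <= 65")
        glo, ghi = self.followup_gap_range
        if not (0.0 < glo <= ghi):
            raise ConfigurationError("followup_gap_range: min must be > 0 and <= max")
        names = [s.name for s in self.factor_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("factor_specs: duplicate factor names")
        for which in ("incidence", "remittance"):
            coefs = getattr(self, which)
            if coefs is None:
                raise ConfigurationError(f"{which}: hazard coefficients are required")
            if len(coefs.band_log_rates) != self.bands.n_bands:
                raise ConfigurationError(
                    f"{which}.band_log_rates: expected {self.bands.n_bands} values"
                )
            known = {f for spec in self.factor_specs for f in spec.feature_names}
            unknown = set(coefs.factors) - known
            if unknown:
                raise ConfigurationError(f"{which}.factors: unknown features {sorted(unknown)}")
        if self.baseline_prevalence is None:
            raise ConfigurationError("baseline_prevalence: coefficients are required")

    @property
    def factor_names(self) -> list[str]:
        return [s.name for s in self.factor_specs]

    def factor_spec(self, name: str) -> FactorSpec:
        for spec in self.factor_specs:
            if spec.name == name:
                return spec
        raise ConfigurationError(f"factor_specs: no factor named {name!r}")

    # ---------------------------------------------------------------- truth

    def covariate_log_multiplier(self, which: str, female, education_years,
                                 factor_values: dict[str, np.ndarray] | None = None):
        """Non-band part of the ground-truth log hazard (vectorised)."""
        coefs: HazardCoefficients = getattr(self, which)
        lp = (
            coefs.female * np.asarray(female, dtype=float)
            + coefs.education_per_year
            * (np.asarray(education_years, dtype=float) - EDUCATION_CENTER)
        )
        if factor_values:
            for spec in self.factor_specs:
                feats = spec.features_of_level(factor_values[spec.name])
                for j, fname in enumerate(spec.feature_names):
                    c = coefs.factors.get(fname, 0.0)
                    if c != 0.0:
                        lp = lp + c * feats[..., j]
        return lp

    def _factor_multiplier_expectation(self, which: str, education_years: int) -> float:
        """E[exp(sum of factor terms)] under the education-conditional law."""
        coefs: HazardCoefficients = getattr(self, which)
        total = 1.0
        for spec in self.factor_specs:
            feats = spec.features_of_level(np.asarray(spec.levels))
            term = np.zeros(len(spec.levels))
            for j, fname in enumerate(spec.feature_names):
                term += coefs.factors.get(fname, 0.0) * feats[:, j]
            total *= float(np.sum(spec.probs(education_years) * np.exp(term)))
        return total

    def _factor_mean_log_multiplier(self, which: str, education_years: int) -> float:
        """Sum of factor coefficients times education-conditional mean features."""
        coefs: HazardCoefficients = getattr(self, which)
        total = 0.0
        for spec in self.factor_specs:
            feats = spec.features_of_level(np.asarray(spec.levels))
            mean_feats = spec.probs(education_years) @ feats
            for j, fname in enumerate(spec.feature_names):
                total += coefs.factors.get(fname, 0.0) * mean_feats[j]
        return total


# --------------------------------------------------------------------------
# Ground-truth summaries
# --------------------------------------------------------------------------

def true_rate_table(config: GeneratorConfig, at_mean_factors: bool = False) -> RateTable:
    """The exact stratum x band hazards implied by the generator's truth.

    By default this is the stratum-average hazard, i.e. the band rate
    ``exp(band + sex + education terms)`` scaled by the population mean of
    the factor multiplier ``E[exp(factor terms) | education]`` — the target
    that a marginal-standardisation estimator averaging per-record hazards
    is consistent for.  With ``at_mean_factors=True`` the multiplier is
    instead evaluated at the mean factor features (``exp`` of the mean
    linear predictor).
    """
    incidence: dict[Stratum, np.ndarray] = {}
    remittance: dict[Stratum, np.ndarray] = {}
    prevalence: dict[Stratum, float] = {}
    for sex, edu in DEFAULT_STRATA:
        female = 1.0 if sex == "female" else 0.0
        for which, store in (("incidence", incidence), ("remittance", remittance)):
            coefs: HazardCoefficients = getattr(config, which)
            base = np.exp(np.asarray(coefs.band_log_rates))
            sexedu = np.exp(
                coefs.female * female + coefs.education_per_year * (edu - EDUCATION_CENTER)
            )
            if at_mean_factors:
                mult = np.exp(config._factor_mean_log_multiplier(which, edu))
            else:
                mult = config._factor_multiplier_expectation(which, edu)
            store[(sex, edu)] = base * sexedu * mult
        prevalence[(sex, edu)] = float(
            config.baseline_prevalence.probability(female, edu, START_AGE)
        )
    return RateTable(config.bands, incidence, remittance, prevalence, provenance="ground_truth")


def _joint_factor_log_multiplier(config: GeneratorConfig, which: str,
                                 education_years: int) -> tuple[np.ndarray, np.ndarray]:
    """Joint pmf of the summed factor term: (values, probabilities).

    Factors are independent given education, so the joint support is the
    outer sum over the per-factor terms (a few thousand atoms).
    """
    values = np.zeros(1)
    probs = np.ones(1)
    coefs: HazardCoefficients = getattr(config, which)
    for spec in config.factor_specs:
        feats = spec.features_of_level(np.asarray(spec.levels))
        term = np.zeros(len(spec.levels))
        for j, fname in enumerate(spec.feature_names):
            term += coefs.factors.get(fname, 0.0) * feats[:, j]
        p = spec.probs(education_years)
        keep = p > 0
        values = (values[:, None] + term[None, keep]).ravel()
        probs = (probs[:, None] * p[None, keep]).ravel()
    return values, probs


def true_life_course_prevalence(config: GeneratorConfig, stratum: Stratum) -> float:
    """Exact ground-truth ever-MDD probability over ages 18-65 for a stratum.

    First entry into MDD depends only on the incidence hazard, so
    P(ever) = E_x[p18 + (1 - p18)(1 - exp(-Lambda0 e^{lp(x)}))], averaged
    over the education-conditional joint factor distribution.
    """
    sex, edu = stratum
    female = 1.0 if sex == "female" else 0.0
    coefs = config.incidence
    base = np.exp(np.asarray(coefs.band_log_rates))
    lambda0 = float(np.sum(base * config.bands.widths)) * np.exp(
        coefs.female * female + coefs.education_per_year * (edu - EDUCATION_CENTER)
    )
    lp, w = _joint_factor_log_multiplier(config, "incidence", edu)
    survive = float(np.sum(w * np.exp(-lambda0 * np.exp(lp))))
    p18 = float(config.baseline_prevalence.probability(female, edu, START_AGE))
    return p18 + (1.0 - p18) * (1.0 - survive)


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

COHORT_BASE_COLUMNS = [
    "id", "sex", "education_years", "age_baseline",
    "mdd_baseline", "followup_gap", "mdd_followup",
]


class _OpenBands:
    """Band partition without the [18, 65] endpoint constraint.

    Follow-up intervals can extend past age 65; the generator keeps the
    final band's hazard in force beyond 65 by extending the partition.
    """

    def __init__(self, boundaries: np.ndarray):
        self._array = np.asarray(boundaries, dtype=float)

    @property
    def n_bands(self) -> int:
        return self._array.size - 1

    @property
    def starts(self) -> np.ndarray:
        return self._array[:-1]

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self._array)

    def index_of(self, age):
        idx = np.searchsorted(self._array, np.asarray(age, dtype=float), side="right") - 1
        return np.clip(idx, 0, self.n_bands - 1)


def _draw_categorical(rng: np.random.Generator, levels, probs, size: int) -> np.ndarray:
    cum = np.cumsum(np.asarray(probs, dtype=float))
    idx = np.searchsorted(cum, rng.random(size), side="right")
    return np.asarray(levels)[np.clip(idx, 0, len(levels) - 1)]


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic two-wave panel cohort; deterministic given the seed.

    Returns a frame with one row per participant: the ``PanelRecord``
    columns (id, sex, education_years, age_baseline, mdd_baseline,
    followup_gap, mdd_followup) followed by one column per modifiable
    factor (NaN where masked).
    """
    n = config.n_individuals
    rng = np.random.Generator(np.random.Philox(key=int(config.seed)))
    factor_cols = {s.name: np.empty(n, dtype=float) for s in config.factor_specs}
    if n == 0:
        return pd.DataFrame(
            {c: pd.Series(dtype=float) for c in COHORT_BASE_COLUMNS + config.factor_names}
        )

    female = rng.random(n) < config.p_female
    low = rng.random(n) < config.p_low_education
    education = np.where(low, EDUCATION_LOW, EDUCATION_HIGH)
    lo, hi = config.baseline_age_range
    age0 = lo + (hi - lo) * rng.random(n)
    glo, ghi = config.followup_gap_range
    gap = glo + (ghi - glo) * rng.random(n)

    for spec in config.factor_specs:
        vals = np.empty(n, dtype=float)
        for edu in (EDUCATION_LOW, EDUCATION_HIGH):
            mask = education == edu
            vals[mask] = _draw_categorical(rng, spec.levels, spec.probs(edu), int(mask.sum()))
        factor_cols[spec.name] = vals

    p_base = config.baseline_prevalence.probability(female, education, age0)
    mdd0 = rng.random(n) < p_base

    # exact event-history simulation of the ground-truth process over the gap
    m_inc = np.exp(config.covariate_log_multiplier("incidence", female, education, factor_cols))
    m_rem = np.exp(config.covariate_log_multiplier("remittance", female, education, factor_cols))
    boundaries = np.asarray(config.bands.boundaries)
    ext = _OpenBands(np.append(boundaries, boundaries[-1] + (ghi - 0.0) + 1.0))
    inc_base = np.exp(np.append(config.incidence.band_log_rates,
                                config.incidence.band_log_rates[-1]))
    rem_base = np.exp(np.append(config.remittance.band_log_rates,
                                config.remittance.band_log_rates[-1]))
    mdd1, _ = simulate_two_state(
        inc_base, rem_base, ext, mdd0.copy(), age0, age0 + gap, rng,
        m_inc=m_inc, m_rem=m_rem, record_transitions=False,
    )

    frame = pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": np.where(female, "female", "male"),
            "education_years": education,
            "age_baseline": age0,
            "mdd_baseline": mdd0.astype(int),
            "followup_gap": gap,
            "mdd_followup": mdd1.astype(int),
        }
    )
    for name, vals in factor_cols.items():
        if config.missing_rate > 0:
            vals = np.where(rng.random(n) < config.missing_rate, np.nan, vals)
        frame[name] = vals
    return frame


def validate_cohort(frame: pd.DataFrame, factor_names=()) -> None:
    """Raise if the frame violates the panel-record invariants."""
    missing = [c for c in COHORT_BASE_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"cohort: missing columns {missing}")
    if len(frame) == 0:
        return
    if not frame["sex"].isin(["female", "male"]).all():
        raise ConfigurationError("cohort.sex: values must be 'female' or 'male'")
    if not frame["education_years"].isin(list((EDUCATION_LOW, EDUCATION_HIGH))).all():
        raise ConfigurationError("cohort.education_years: values must be 10 or 16")
    ages = frame["age_baseline"]
    if (ages < START_AGE).any() or (ages > END_AGE).any():
        raise ConfigurationError("cohort.age_baseline: outside [18, 65]")
    if (frame["followup_gap"] <= 0).any():
        raise ConfigurationError("cohort.followup_gap: must be > 0")
    for col in ("mdd_baseline", "mdd_followup"):
        if not frame[col].isin([0, 1]).all():
            raise ConfigurationError(f"cohort.{col}: must be binary")
    absent = [f for f in factor_names if f not in frame.columns]
    if absent:
        raise ConfigurationError(f"cohort: missing factor columns {absent}")


def write_cohort(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    validate_cohort(frame)
    return frame


# --------------------------------------------------------------------------
# Default study conditions
# --------------------------------------------------------------------------

#: Minor lifestyle factors carrying a small share of the education effect.
_MINOR_FACTORS = (
    "physical_activity", "alcohol_intake", "diet_quality", "sleep_duration", "network_size",
)


def default_factor_specs() -> tuple[FactorSpec, ...]:
    """Nine modifiable factors with education-graded distributions.

    Codes are risk-ordered (higher = less favourable).  The three factors
    that dominate the education -> MDD mediation are quality of social
    contacts (5-level ordinal), health literacy (tertiles) and smoking
    (never/former/current, entered as two indicators); the remaining six
    carry small effects.
    """
    specs = [
        FactorSpec(
            "quality_social_contacts",
            levels=(0, 1, 2, 3, 4),
            probs_low=(0.12, 0.20, 0.25, 0.25, 0.18),
            probs_high=(0.30, 0.30, 0.20, 0.15, 0.05),
        ),
        FactorSpec(
            "health_literacy",
            levels=(0, 1, 2),
            probs_low=(0.22, 0.38, 0.40),
            probs_high=(0.50, 0.35, 0.15),
        ),
        FactorSpec(
            "smoking",
            levels=(0, 1, 2),
            probs_low=(0.38, 0.32, 0.30),
            probs_high=(0.58, 0.30, 0.12),
            encoding=FACTOR_ENCODING_ONEHOT,
        ),
        FactorSpec(
            "partner_status",
            levels=(0, 1),
            probs_low=(0.70, 0.30),
            probs_high=(0.78, 0.22),
        ),
    ]
    for name in _MINOR_FACTORS:
        specs.append(
            FactorSpec(
                name,
                levels=(0, 1, 2),
                probs_low=(0.40, 0.38, 0.22),
                probs_high=(0.50, 0.35, 0.15),
            )
        )
    return tuple(specs)


_DEFAULT_INCIDENCE_FACTOR_COEFS = {
    "quality_social_contacts": 0.19,
    "health_literacy": 0.21,
    "smoking_1": 0.08,   # former
    "smoking_2": 0.40,   # current
    "partner_status": 0.10,
    **{name: 0.06 for name in _MINOR_FACTORS},
}

_DEFAULT_REMITTANCE_FACTOR_COEFS = {
    "quality_social_contacts": -0.08,
    "health_literacy": -0.06,
    "smoking_1": -0.02,
    "smoking_2": -0.08,
    "partner_status": -0.03,
    **{name: -0.02 for name in _MINOR_FACTORS},
}

#: Relative age profiles (exposure-weighted mean 1 after normalisation):
#: incidence declines with age, remittance declines mildly.
_INCIDENCE_AGE_PROFILE = (1.35, 1.30, 1.20, 1.10, 1.00, 0.92, 0.85, 0.78, 0.72, 0.70)
_REMITTANCE_AGE_PROFILE = (1.10, 1.08, 1.05, 1.02, 1.00, 0.98, 0.95, 0.92, 0.90, 0.88)

#: Mean hazards targeted for the female low-education stratum, anchored to
#: published life-course prevalence (~35% ever-MDD) and point prevalence
#: (<6% in any year) for that group.
_TARGET_MEAN_INCIDENCE_FEMALE_LOW = 0.008383
_TARGET_MEAN_REMITTANCE_FEMALE_LOW = 0.184


def _calibrated_band_log_rates(which: str, profile, target_female_low: float,
                               female_coef: float, edu_coef: float,
                               factor_coefs: dict, specs: tuple[FactorSpec, ...],
                               bands: AgeBands) -> tuple[float, ...]:
    """Band intercepts such that the female/low stratum mean hazard over the
    whole age span equals the target."""
    profile = np.asarray(profile, dtype=float)
    profile = profile / (np.sum(profile * bands.widths) / np.sum(bands.widths))
    probe = GeneratorConfig(
        n_individuals=0, seed=0, factor_specs=specs,
        incidence=HazardCoefficients((0.0,) * bands.n_bands, factors=dict(factor_coefs)),
        remittance=HazardCoefficients((0.0,) * bands.n_bands, factors=dict(factor_coefs)),
        baseline_prevalence=BaselinePrevalenceCoefficients(0.0),
        bands=bands,
    )
    factor_mult = probe._factor_multiplier_expectation("incidence", EDUCATION_LOW)
    base = (
        np.log(target_female_low)
        - female_coef
        - edu_coef * (EDUCATION_LOW - EDUCATION_CENTER)
        - np.log(factor_mult)
    )
    return tuple(float(v) for v in base + np.log(profile))


def default_config(n_individuals: int = 50_000, seed: int = 0, **overrides) -> GeneratorConfig:
    """The default study conditions for the synthetic cohort.

    Ground-truth hazards are anchored so the four strata's ever-MDD
    probabilities land near the published life-course prevalences
    (35.3/14.5/28.6/11.3%), with roughly a third of the education effect on
    incidence mediated by quality of social contacts, health literacy and
    smoking together.  See docs/methods.md for the full derivation.
    """
    bands = AgeBands.five_year()
    specs = default_factor_specs()
    incidence = HazardCoefficients(
        band_log_rates=_calibrated_band_log_rates(
            "incidence", _INCIDENCE_AGE_PROFILE, _TARGET_MEAN_INCIDENCE_FEMALE_LOW,
            0.26, -0.1034, _DEFAULT_INCIDENCE_FACTOR_COEFS, specs, bands,
        ),
        female=0.26,
        education_per_year=-0.1034,
        factors=dict(_DEFAULT_INCIDENCE_FACTOR_COEFS),
    )
    remittance = HazardCoefficients(
        band_log_rates=_calibrated_band_log_rates(
            "remittance", _REMITTANCE_AGE_PROFILE, _TARGET_MEAN_REMITTANCE_FEMALE_LOW,
            0.12, 0.035, _DEFAULT_REMITTANCE_FACTOR_COEFS, specs, bands,
        ),
        female=0.12,
        education_per_year=0.035,
        factors=dict(_DEFAULT_REMITTANCE_FACTOR_COEFS),
    )
    baseline = BaselinePrevalenceCoefficients(
        intercept=-3.97, female=0.29, education_per_year=-0.1667, age_per_year=0.004,
    )
    params = dict(
        n_individuals=n_individuals,
        seed=seed,
        factor_specs=specs,
        incidence=incidence,
        remittance=remittance,
        baseline_prevalence=baseline,
        missing_rate=0.05,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


#: Coarse partition giving every band ~2000 transitions per direction at
#: n = 50 000 under :func:`recovery_config`; at that resolution the 10%
#: relative-error budget for band-hazard recovery sits several standard
#: errors above the estimator's sampling noise.
RECOVERY_BANDS = AgeBands((18.0, 30.0, 42.0, 54.0, 65.0))


def recovery_config(n_individuals: int = 50_000, seed: int = 0,
                    bands: AgeBands | None = None, **overrides) -> GeneratorConfig:
    """An event-rich configuration for parameter-recovery studies.

    Band-level hazard recovery from a finite two-wave panel is limited by
    the number of observed transitions per band in each direction, not by
    the realism of the rates.  This configuration therefore balances the
    two directions (incidence and remittance both ~0.15/year, age-18
    prevalence ~0.45 so both risk sets are large), uses gently varying age
    profiles, and draws follow-up gaps of 3-5 years so that every band
    observes on the order of a thousand transitions per direction at
    n = 50 000.  Two small-effect factors exercise the covariate machinery
    without adding material hazard heterogeneity.

    ``bands`` defaults to the five-year partition; pass
    :data:`RECOVERY_BANDS` for band-level recovery checks whose per-band
    sampling error is small relative to a 10% accuracy budget.
    """
    bands = bands or AgeBands.five_year()
    nb = bands.n_bands
    specs = (
        FactorSpec(
            "quality_social_contacts",
            levels=(0, 1, 2),
            probs_low=(0.25, 0.40, 0.35),
            probs_high=(0.45, 0.35, 0.20),
        ),
        FactorSpec(
            "health_literacy",
            levels=(0, 1, 2),
            probs_low=(0.30, 0.40, 0.30),
            probs_high=(0.50, 0.30, 0.20),
        ),
    )
    inc_profile = 0.98 ** np.arange(nb)
    inc_profile /= np.sum(inc_profile * bands.widths) / np.sum(bands.widths)
    rem_profile = 1.02 ** np.arange(nb)
    rem_profile /= np.sum(rem_profile * bands.widths) / np.sum(bands.widths)
    params = dict(
        n_individuals=n_individuals,
        seed=seed,
        followup_gap_range=(2.5, 4.0),
        factor_specs=specs,
        incidence=HazardCoefficients(
            band_log_rates=tuple(np.log(0.15 * inc_profile)),
            female=0.10,
            education_per_year=-0.03,
            factors={"quality_social_contacts": 0.10, "health_literacy": 0.08},
        ),
        remittance=HazardCoefficients(
            band_log_rates=tuple(np.log(0.25 * rem_profile)),
            female=0.05,
            education_per_year=0.01,
            factors={"quality_social_contacts": -0.05, "health_literacy": -0.04},
        ),
        baseline_prevalence=BaselinePrevalenceCoefficients(
            intercept=-0.2007, female=0.10, education_per_year=-0.03, age_per_year=0.0,
        ),
        missing_rate=0.02,
        bands=bands,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


# --------------------------------------------------------------------------
# YAML round trip
# --------------------------------------------------------------------------

def config_to_yaml(config: GeneratorConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["bands"] = list(config.bands.boundaries)
    d["factor_specs"] = [dataclasses.asdict(s) for s in config.factor_specs]
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(d), fh, sort_keys=False)


def config_from_yaml(path) -> GeneratorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["bands"] = AgeBands(tuple(d["bands"]))
    d["factor_specs"] = tuple(
        FactorSpec(
            name=s["name"], levels=tuple(s["levels"]), probs_low=tuple(s["probs_low"]),
            probs_high=tuple(s["probs_high"]), encoding=s.get("encoding", "ordinal"),
        )
        for s in d["factor_specs"]
    )
    for which in ("incidence", "remittance"):
        c = d[which]
        d[which] = HazardCoefficients(
            band_log_rates=tuple(c["band_log_rates"]), female=c["female"],
            education_per_year=c["education_per_year"], factors=dict(c["factors"]),
        )
    b = d["baseline_prevalence"]
    d["baseline_prevalence"] = BaselinePrevalenceCoefficients(
        intercept=b["intercept"], female=b["female"],
        education_per_year=b["education_per_year"], age_per_year=b["age_per_year"],
    )
    d["education_years_levels"] = tuple(d["education_years_levels"])
    d["baseline_age_range"] = tuple(d["baseline_age_range"])
    d["followup_gap_range"] = tuple(d["followup_gap_range"])
    return GeneratorConfig(**d)


def _plain(obj):
    """Recursively convert numpy scalars/tuples for YAML serialisation."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items() if k != "_array"}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, AgeBands):
        return list(obj.boundaries)
    return obj
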