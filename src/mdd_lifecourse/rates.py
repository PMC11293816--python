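"""Estimating age-banded transition rates from two-wave panel data.

The estimation pipeline mirrors how transition rates are derived from a
prospective cohort: logistic regression of the follow-up state on age band,
sex and years of education (optionally plus modifiable factors) within the
appropriate risk set, followed by conversion of interval transition
probabilities into continuous-time hazards.

Because a follow-up interval can contain several transitions (a person can
develop MDD and remit before being re-interviewed), the default conversion
inverts the closed-form interval probabilities of the two-state process
jointly: with interval probabilities p01 (healthy -> MDD observed) and p10
(MDD -> healthy observed) over a gap t,

    lam + mu = -ln(1 - p01 - p10) / t,      lam = (lam + mu) p01 / (p01 + p10),

which reduces to the single-direction exponential inversion
``-ln(1 - p) / t`` when the opposing rate is zero.  A ``method="naive"``
mode applies the single-direction inversion to each transition separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bands import AgeBands
from .cohort import EDUCATION_CENTER, FactorSpec
from .exceptions import ConfigurationError, EstimationError
from .ratetable import DEFAULT_STRATA, RateTable, Stratum

logger = logging.getLogger(__name__)

INCIDENCE = "incidence"
REMITTANCE = "remittance"

#: Fitted log-odds above this magnitude are treated as (quasi-)separation.
_SEPARATION_BOUND = 15.0


# --------------------------------------------------------------------------
# Probability <-> hazard
# --------------------------------------------------------------------------

def probability_to_hazard(p, gap):
    """Constant hazard whose interval transition probability over ``gap`` is ``p``.

    Inverts p = 1 - exp(-lam * gap), i.e. returns ``-ln(1 - p) / gap``
    (events per person-year); monotone increasing in ``p``.
    """
    p = np.asarray(p, dtype=float)
    gap = np.asarray(gap, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must be in [0, 1)")
    if np.any(p >= 1):
        raise ValueError("p = 1 implies an infinite hazard")
    if np.any(gap <= 0):
        raise ValueError("gap must be > 0")
    out = -np.log1p(-p) / gap
    return float(out) if out.ndim == 0 else out


def hazard_to_probability(hazard, gap):
    """Interval transition probability 1 - exp(-hazard * gap)."""
    hazard = np.asarray(hazard, dtype=float)
    gap = np.asarray(gap, dtype=float)
    if np.any(hazard < 0) or np.any(gap <= 0):
        raise ValueError("hazard must be >= 0 and gap > 0")
    out = -np.expm1(-hazard * gap)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# Imputation
# --------------------------------------------------------------------------

def impute_factors(cohort: pd.DataFrame, factor_names, seed: int = 0,
                   factor_specs: dict[str, FactorSpec] | None = None) -> pd.DataFrame:
    """Single stochastic-regression imputation of missing factor cells.

    Each factor is regressed (OLS) on sex, education years and baseline age
    among observed rows; missing cells get the prediction plus a Gaussian
    residual draw, rounded to the nearest valid code.  Deterministic given
    the seed.  Documented as a replaceable placeholder for a study-specific
    missing-data procedure.
    """
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    X = np.column_stack(
        [
            np.ones(len(cohort)),
            (cohort["sex"] == "female").to_numpy(float),
            cohort["education_years"].to_numpy(float) - EDUCATION_CENTER,
            cohort["age_baseline"].to_numpy(float),
        ]
    )
    for name in factor_names:
        y = out[name].to_numpy(float)
        obs = ~np.isnan(y)
        if obs.all():
            continue
        if not obs.any():
            raise EstimationError(f"factor {name!r} has no observed values to impute from")
        beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
        resid_sd = float(np.std(y[obs] - X[obs] @ beta, ddof=X.shape[1]))
        pred = X[~obs] @ beta + rng.normal(0.0, resid_sd, size=int((~obs).sum()))
        if factor_specs and name in factor_specs:
            levels = np.asarray(factor_specs[name].levels, dtype=float)
        else:
            levels = np.unique(y[obs])
        nearest = levels[np.argmin(np.abs(pred[:, None] - levels[None, :]), axis=1)]
        y[~obs] = nearest
        out[name] = y
    return out


# --------------------------------------------------------------------------
# Transition models
# --------------------------------------------------------------------------

@dataclass
class _Fit:
    columns: list[str]
    params: np.ndarray
    bse: np.ndarray
    missing_bands: list[int]
    n_events: int
    n_records: int


@dataclass
class TransitionModel:
    """A fitted logistic model for one transition direction.

    ``stratified=True`` (the default) fits a separate model per sex x
    education stratum with age-band indicators (+ extra covariates);
    ``stratified=False`` fits one pooled model with additional ``female``
    and centred ``education_years`` terms, which is the form used for the
    mediation screen.
    """

    direction: str
    bands: AgeBands
    stratified: bool
    extra_covariates: tuple[str, ...]
    factor_specs: dict[str, FactorSpec]
    fits: dict  # Stratum -> _Fit, or {"pooled": _Fit}

    @property
    def coefficients(self) -> pd.Series:
        """Named log-odds coefficients (pooled fit) or a stacked per-stratum set."""
        if not self.stratified:
            fit = self.fits["pooled"]
            return pd.Series(fit.params, index=fit.columns)
        frames = {}
        for stratum, fit in self.fits.items():
            frames[f"{stratum[0]}:{stratum[1]}"] = pd.Series(fit.params, index=fit.columns)
        return pd.concat(frames)

    @property
    def standard_errors(self) -> pd.Series:
        """Approximate standard errors aligned with :attr:`coefficients`."""
        if not self.stratified:
            fit = self.fits["pooled"]
            return pd.Series(fit.bse, index=fit.columns)
        frames = {}
        for stratum, fit in self.fits.items():
            frames[f"{stratum[0]}:{stratum[1]}"] = pd.Series(fit.bse, index=fit.columns)
        return pd.concat(frames)

    @property
    def feature_names(self) -> set[str]:
        names: set[str] = set()
        for fit in self.fits.values():
            names.update(fit.columns)
        return names

    def includes_factor(self, name: str) -> bool:
        return name in self.extra_covariates

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Predicted interval transition probability per row."""
        p = np.empty(len(df))
        if self.stratified:
            covered = np.zeros(len(df), dtype=bool)
            for stratum, fit in self.fits.items():
                mask = (
                    (df["sex"] == stratum[0]) & (df["education_years"] == stratum[1])
                ).to_numpy()
                if mask.any():
                    p[mask] = self._predict_one(df[mask], fit)
                covered |= mask
            if not covered.all():
                raise EstimationError("prediction requested for an unfitted stratum")
        else:
            p[:] = self._predict_one(df, self.fits["pooled"])
        return p

    def _predict_one(self, df: pd.DataFrame, fit: _Fit) -> np.ndarray:
        idx = self.bands.index_of(df["age_baseline"].to_numpy(float))
        bad = np.isin(idx, fit.missing_bands)
        if bad.any():
            labels = [self.bands.labels[b] for b in sorted(set(idx[bad]))]
            raise EstimationError(
                f"{self.direction}: no at-risk records were available to fit band(s) "
                f"{labels}; cannot predict for records in them"
            )
        X = _design_matrix(
            df, self.bands, not self.stratified, self.extra_covariates, self.factor_specs
        )
        X = X[fit.columns].to_numpy(float)
        return 1.0 / (1.0 + np.exp(-(X @ fit.params)))


def _design_matrix(df, bands: AgeBands, include_sex_edu: bool, extra, specs,
                   include_gap: bool = True) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    idx = bands.index_of(df["age_baseline"].to_numpy(float))
    for b in range(bands.n_bands):
        cols[f"band_{b}"] = (idx == b).astype(float)
    if include_gap:
        # exposure term: predictions must track each record's follow-up gap,
        # otherwise the record-level hazard conversion picks up E[1/gap]
        # curvature bias under irregular gaps
        cols["log_gap"] = np.log(df["followup_gap"].to_numpy(float))
    if include_sex_edu:
        cols["female"] = (df["sex"] == "female").to_numpy(float)
        cols["education_years"] = df["education_years"].to_numpy(float) - EDUCATION_CENTER
    for name in extra:
        values = df[name].to_numpy(float)
        if np.isnan(values).any():
            raise EstimationError(
                f"covariate {name!r} contains missing values; impute before fitting"
            )
        spec = specs.get(name) if specs else None
        if spec is None:
            cols[name] = values
        else:
            feats = spec.features_of_level(values)
            for j, fname in enumerate(spec.feature_names):
                cols[fname] = feats[..., j]
    return pd.DataFrame(cols, index=df.index)


def _risk_set(cohort: pd.DataFrame, direction: str) -> tuple[pd.DataFrame, np.ndarray]:
    if direction == INCIDENCE:
        sub = cohort[cohort["mdd_baseline"] == 0]
        y = sub["mdd_followup"].to_numpy(float)
    elif direction == REMITTANCE:
        sub = cohort[cohort["mdd_baseline"] == 1]
        y = 1.0 - sub["mdd_followup"].to_numpy(float)
    else:
        raise ConfigurationError(f"direction: must be incidence or remittance, got {direction!r}")
    return sub, y


def _fit_logistic(X: pd.DataFrame, y: np.ndarray, direction: str, label: str) -> _Fit:
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise EstimationError(
            f"{direction} ({label}): need at least 1 event and 1 non-event "
            f"(got {n_events} events out of {len(y)} records)"
        )
    # drop unpopulated band indicators, plus degenerate covariates (e.g. a
    # constant log-gap column when all gaps are equal, which would be
    # collinear with the band indicators)
    keep = [
        c for c in X.columns
        if X[c].abs().sum() > 0 and (c.startswith("band_") or X[c].std() > 1e-10)
    ]
    missing_bands = [
        int(c.split("_")[1]) for c in X.columns if c.startswith("band_") and c not in keep
    ]
    Xk = X[keep].to_numpy(float)
    if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        raise EstimationError(f"{direction} ({label}): design matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, Xk, family=sm.families.Binomial()).fit(maxiter=200)
        except Exception as exc:  # statsmodels raises several flavours here
            raise EstimationError(f"{direction} ({label}): logistic fit failed: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.any(np.abs(params) > _SEPARATION_BOUND):
        raise EstimationError(
            f"{direction} ({label}): complete or quasi-complete separation detected "
            f"(max |log-odds| = {np.nanmax(np.abs(params)):.1f})"
        )
    return _Fit(keep, params, np.asarray(res.bse, dtype=float), missing_bands,
                n_events, len(y))


def fit_transition_model(
    cohort: pd.DataFrame,
    direction: str,
    extra_covariates=(),
    factor_specs: dict[str, FactorSpec] | None = None,
    stratified: bool = True,
    bands: AgeBands | None = None,
) -> TransitionModel:
    """Fit the logistic transition model for one direction.

    Incidence uses the baseline-healthy risk set with outcome
    ``mdd_followup``; remittance uses the baseline-MDD risk set with outcome
    ``1 - mdd_followup``.  Raises :class:`EstimationError` on empty risk
    sets, missing events or separation.
    """
    bands = bands or AgeBands.five_year()
    factor_specs = factor_specs or {}
    extra = tuple(extra_covariates)
    sub, y = _risk_set(cohort, direction)
    if len(sub) == 0:
        raise EstimationError(f"{direction}: empty risk set")
    fits: dict = {}
    if stratified:
        for stratum in DEFAULT_STRATA:
            mask = (sub["sex"] == stratum[0]) & (sub["education_years"] == stratum[1])
            if not mask.any():
                raise EstimationError(f"{direction}: stratum {stratum} has no at-risk records")
            X = _design_matrix(sub[mask], bands, False, extra, factor_specs)
            fits[stratum] = _fit_logistic(X, y[mask.to_numpy()], direction, str(stratum))
    else:
        X = _design_matrix(sub, bands, True, extra, factor_specs)
        fits["pooled"] = _fit_logistic(X, y, direction, "pooled")
    return TransitionModel(direction, bands, stratified, extra, factor_specs, fits)


# --------------------------------------------------------------------------
# Baseline prevalence
# --------------------------------------------------------------------------

def fit_baseline_prevalence(cohort: pd.DataFrame, max_age: float = 20.0) -> dict[Stratum, float]:
    """Per-stratum MDD probability at age 18.

    Fits a logistic model of baseline MDD on sex and education among
    records aged at most ``max_age`` and predicts per stratum; falls back
    to the stratum's empirical proportion when the model is degenerate
    (rank deficiency, separation, no variation).
    """
    if len(cohort) == 0:
        raise EstimationError("baseline prevalence: empty cohort")
    young = cohort[cohort["age_baseline"] <= max_age]
    strata = [s for s in DEFAULT_STRATA
              if ((cohort["sex"] == s[0]) & (cohort["education_years"] == s[1])).any()]
    out: dict[Stratum, float] = {}
    for stratum in strata:
        mask = (young["sex"] == stratum[0]) & (young["education_years"] == stratum[1])
        if not mask.any():
            raise EstimationError(
                f"baseline prevalence: stratum {stratum} has no records aged <= {max_age}"
            )
    X = np.column_stack(
        [
            np.ones(len(young)),
            (young["sex"] == "female").to_numpy(float),
            young["education_years"].to_numpy(float) - EDUCATION_CENTER,
        ]
    )
    y = young["mdd_baseline"].to_numpy(float)
    params = None
    if 0 < y.sum() < len(y) and np.linalg.matrix_rank(X) == X.shape[1]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
                if np.all(np.isfinite(res.params)) and np.all(
                    np.abs(res.params) < _SEPARATION_BOUND
                ):
                    params = np.asarray(res.params, dtype=float)
            except Exception:
                params = None
    for stratum in strata:
        mask = (young["sex"] == stratum[0]) & (young["education_years"] == stratum[1])
        if params is not None:
            x = np.array([1.0, 1.0 if stratum[0] == "female" else 0.0,
                          stratum[1] - EDUCATION_CENTER])
            out[stratum] = float(1.0 / (1.0 + np.exp(-x @ params)))
        else:
            logger.warning(
                "baseline prevalence: degenerate model, using empirical proportion for %s",
                stratum,
            )
            out[stratum] = float(young.loc[mask.to_numpy(), "mdd_baseline"].mean())
    return out


# --------------------------------------------------------------------------
# Rate-table construction
# --------------------------------------------------------------------------

def build_rate_table(
    models: tuple[TransitionModel, TransitionModel],
    baseline: dict[Stratum, float],
    bands: AgeBands,
    reference_cohort: pd.DataFrame,
    method: str = "joint",
    provenance: str = "empirical",
) -> RateTable:
    """Marginal standardisation of fitted models into a stratified rate table.

    For every stratum and band, the models' predicted interval transition
    probabilities are computed for each of the stratum's covariate rows
    (all records, supplying the stratum's empirical covariate
    distribution), converted to hazards with that row's follow-up gap, and
    averaged.  ``method="joint"`` inverts both directions together through
    the two-state closed form; ``method="naive"`` converts each direction
    independently with ``probability_to_hazard``.
    """
    if method not in ("joint", "naive"):
        raise ConfigurationError(f"method: unknown conversion method {method!r}")
    inc_model, rem_model = models
    if inc_model.direction != INCIDENCE or rem_model.direction != REMITTANCE:
        raise ConfigurationError("models: expected an (incidence, remittance) pair")
    incidence: dict[Stratum, np.ndarray] = {}
    remittance: dict[Stratum, np.ndarray] = {}
    strata = list(baseline)
    idx_all = bands.index_of(reference_cohort["age_baseline"].to_numpy(float))
    for stratum in strata:
        mask = (
            (reference_cohort["sex"] == stratum[0])
            & (reference_cohort["education_years"] == stratum[1])
        ).to_numpy()
        lam = np.empty(bands.n_bands)
        mu = np.empty(bands.n_bands)
        empty_bands = []
        for b in range(bands.n_bands):
            rows = reference_cohort[mask & (idx_all == b)]
            if len(rows) == 0:
                empty_bands.append(bands.labels[b])
                continue
            gap = rows["followup_gap"].to_numpy(float)
            p01 = inc_model.predict(rows)
            p10 = rem_model.predict(rows)
            if method == "joint":
                tot = np.clip(p01 + p10, None, 1.0 - 1e-12)
                rho = probability_to_hazard(tot, gap)
                with np.errstate(invalid="ignore", divide="ignore"):
                    lam_rows = np.where(tot > 0, rho * p01 / tot, 0.0)
                    mu_rows = np.where(tot > 0, rho * p10 / tot, 0.0)
            else:
                lam_rows = probability_to_hazard(np.clip(p01, None, 1.0 - 1e-12), gap)
                mu_rows = probability_to_hazard(np.clip(p10, None, 1.0 - 1e-12), gap)
            lam[b] = lam_rows.mean()
            mu[b] = mu_rows.mean()
        if empty_bands:
            raise EstimationError(
                f"stratum {stratum}: no at-risk records in band(s) {empty_bands}"
            )
        incidence[stratum] = lam
        remittance[stratum] = mu
    return RateTable(bands, incidence, remittance, dict(baseline), provenance=provenance)


def estimate_rate_table(
    cohort: pd.DataFrame,
    bands: AgeBands | None = None,
    extra_covariates=(),
    factor_specs: dict[str, FactorSpec] | None = None,
    stratified: bool = True,
    method: str = "joint",
    impute_seed: int = 0,
) -> RateTable:
    """End-to-end estimation: impute -> baseline prevalence -> transition
    models -> marginally standardised rate table."""
    bands = bands or AgeBands.five_year()
    factor_names = [c for c in cohort.columns if c not in
                    ("id", "sex", "education_years", "age_baseline",
                     "mdd_baseline", "followup_gap", "mdd_followup")]
    cohort = impute_factors(cohort, factor_names, seed=impute_seed, factor_specs=factor_specs)
    baseline = fit_baseline_prevalence(cohort)
    inc = fit_transition_model(cohort, INCIDENCE, extra_covariates, factor_specs,
                               stratified, bands)
    rem = fit_transition_model(cohort, REMITTANCE, extra_covariates, factor_specs,
                               stratified, bands)
    return build_rate_table((inc, rem), baseline, bands, cohort, method=method)


# --------------------------------------------------------------------------
# Representativeness
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PPRResult:
    ratio: float
    adequate: bool  # 0.8 <= ratio <= 1.2


def participation_prevalence_ratio(
    subgroup_count_in_sample: int,
    sample_size: int,
    subgroup_count_in_population: int,
    population_size: int,
) -> PPRResult:
    """Participation-to-prevalence ratio of a subgroup.

    The ratio of the subgroup's share among participants to its share in
    the source population; values between 0.8 and 1.2 indicate adequate
    representation.
    """
    for name, count, size in (
        ("sample", subgroup_count_in_sample, sample_size),
        ("population", subgroup_count_in_population, population_size),
    ):
        if not (isinstance(count, (int, np.integer)) and isinstance(size, (int, np.integer))):
            raise ValueError(f"{name} counts must be integers")
        if count <= 0 or size <= 0:
            raise ValueError(f"{name} counts must be positive")
        if count > size:
            raise ValueError(f"{name} subgroup count exceeds its total")
    ratio = (subgroup_count_in_sample / sample_size) / (
        subgroup_count_in_population / population_size
    )
    return PPRResult(ratio=float(ratio), adequate=bool(0.8 <= ratio <= 1.2))
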