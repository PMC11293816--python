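"""Rate estimation: conversions, logistic fits, marginal standardisation."""

import numpy as np
import pandas as pd
import pytest

import mdd_lifecourse as ml
from mdd_lifecourse.cohort import (
    BaselinePrevalenceCoefficients,
    HazardCoefficients,
    default_config,
)
from mdd_lifecourse.exceptions import EstimationError
from mdd_lifecourse.rates import _Fit, build_rate_table

BANDS = ml.AgeBands.five_year()
NB = BANDS.n_bands


class TestProbabilityHazardConversion:
    @pytest.mark.parametrize(
        "p, gap, expected",
        [
            (0.0, 1.0, 0.0),
            (1.0 - np.exp(-1.0), 1.0, 1.0),
            (0.5, 2.0, np.log(2.0) / 2.0),
        ],
    )
    def test_closed_form_values(self, p, gap, expected):
        assert ml.probability_to_hazard(p, gap) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p, gap", [(1.0, 1.0), (-0.1, 1.0), (0.5, 0.0), (0.5, -2.0)])
    def test_domain_errors(self, p, gap):
        with pytest.raises(ValueError):
            ml.probability_to_hazard(p, gap)

    def test_mutual_inverse_to_machine_precision(self):
        p = np.linspace(0.0, 0.999, 500)
        for gap in (0.5, 1.0, 3.7):
            back = ml.hazard_to_probability(ml.probability_to_hazard(p, gap), gap)
            np.testing.assert_allclose(back, p, atol=1e-12)
        h = np.linspace(0.0, 5.0, 500)
        back_h = ml.probability_to_hazard(ml.hazard_to_probability(h, 2.0), 2.0)
        np.testing.assert_allclose(back_h, h, atol=1e-10)

    def test_monotone_in_p(self):
        p = np.linspace(0.0, 0.99, 100)
        h = ml.probability_to_hazard(p, 1.7)
        assert np.all(np.diff(h) > 0)


class TestBaselinePrevalence:
    def test_all_healthy_young_records_give_zero(self, flat_config):
        frame = ml.generate_cohort(flat_config)
        frame = frame.copy()
        frame["mdd_baseline"] = 0
        prev = ml.fit_baseline_prevalence(frame)
        assert all(v == 0.0 for v in prev.values())

    def test_empirical_proportion_fallback_single_stratum(self):
        # ten printed records, three cases, all in one stratum
        frame = pd.DataFrame(
            dict(
                id=range(10),
                sex=["female"] * 10,
                education_years=[10] * 10,
                age_baseline=[18.5] * 10,
                mdd_baseline=[1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
                followup_gap=[3.0] * 10,
                mdd_followup=[0] * 10,
            )
        )
        prev = ml.fit_baseline_prevalence(frame)
        assert prev[("female", 10)] == pytest.approx(0.30)

    def test_known_coefficients_recovered(self, default_cfg, default_cohort):
        prev = ml.fit_baseline_prevalence(default_cohort)
        truth = ml.true_rate_table(default_cfg).prevalence_at_18
        for s, p_hat in prev.items():
            n_young = (
                (default_cohort["age_baseline"] <= 20)
                & (default_cohort["sex"] == s[0])
                & (default_cohort["education_years"] == s[1])
            ).sum()
            se = np.sqrt(truth[s] * (1 - truth[s]) / n_young)
            assert abs(p_hat - truth[s]) <= 3.5 * se

    def test_stratum_without_young_records_is_an_error(self, flat_config):
        frame = ml.generate_cohort(flat_config)
        frame = frame[
            ~((frame["sex"] == "male") & (frame["education_years"] == 16)
              & (frame["age_baseline"] <= 20))
        ]
        with pytest.raises(EstimationError, match="male"):
            ml.fit_baseline_prevalence(frame)

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(EstimationError):
            ml.fit_baseline_prevalence(pd.DataFrame(columns=["age_baseline"]))


class TestTransitionModel:
    def test_zero_events_raise(self, flat_config):
        frame = ml.generate_cohort(flat_config).copy()
        frame["mdd_followup"] = frame["mdd_baseline"]  # nobody transitions
        with pytest.raises(EstimationError, match="event"):
            ml.fit_transition_model(frame, "incidence")

    def test_null_education_effect_recovered(self):
        cfg = default_config(
            50_000,
            seed=21,
            factor_specs=(),
            missing_rate=0.0,
            incidence=HazardCoefficients((np.log(0.05),) * NB, female=0.2),
            remittance=HazardCoefficients((np.log(0.3),) * NB),
            baseline_prevalence=BaselinePrevalenceCoefficients(-2.0),
        )
        frame = ml.generate_cohort(cfg)
        model = ml.fit_transition_model(frame, "incidence", stratified=False)
        beta = model.coefficients["education_years"]
        se = model.standard_errors["education_years"]
        assert abs(beta) <= 3 * se

    def test_unknown_direction_rejected(self, default_cohort):
        with pytest.raises(ml.ConfigurationError):
            ml.fit_transition_model(default_cohort, "mortality")

    def test_missing_covariate_cells_must_be_imputed_first(self, default_cohort,
                                                           default_specs):
        with pytest.raises(EstimationError, match="impute"):
            ml.fit_transition_model(
                default_cohort, "incidence",
                extra_covariates=("quality_social_contacts",),
                factor_specs=default_specs,
            )

    def test_imputation_fills_all_cells_deterministically(self, default_cohort,
                                                          default_cfg, default_specs):
        names = default_cfg.factor_names
        a = ml.impute_factors(default_cohort, names, seed=4, factor_specs=default_specs)
        b = ml.impute_factors(default_cohort, names, seed=4, factor_specs=default_specs)
        assert not a[names].isna().any().any()
        pd.testing.assert_frame_equal(a, b)
        # imputed values are valid codes
        for spec in default_cfg.factor_specs:
            assert a[spec.name].isin(list(spec.levels)).all()


def _intercept_only_model(direction, theta, bands=BANDS):
    fit = _Fit(
        columns=[f"band_{b}" for b in range(bands.n_bands)],
        params=np.full(bands.n_bands, theta),
        bse=np.full(bands.n_bands, 0.1),
        missing_bands=[],
        n_events=1,
        n_records=1,
    )
    return ml.TransitionModel(direction, bands, False, (), {}, {"pooled": fit})


class TestBuildRateTable:
    def reference_cohort(self, n=2000, gap=3.0):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            dict(
                id=np.arange(n),
                sex=rng.choice(["female", "male"], n),
                education_years=rng.choice([10, 16], n),
                age_baseline=rng.uniform(18, 65, n),
                mdd_baseline=rng.integers(0, 2, n),
                followup_gap=np.full(n, gap),
                mdd_followup=rng.integers(0, 2, n),
            )
        )

    def test_intercept_only_models_give_uniform_hazards(self):
        inc = _intercept_only_model("incidence", -2.0)
        rem = _intercept_only_model("remittance", -1.0)
        baseline = {s: 0.1 for s in ml.DEFAULT_STRATA}
        table = build_rate_table((inc, rem), baseline, BANDS, self.reference_cohort())
        values = np.concatenate([table.incidence[s] for s in ml.DEFAULT_STRATA])
        np.testing.assert_allclose(values, values[0], rtol=1e-9)

    def test_zero_remittance_prediction_gives_zero_hazard(self):
        inc = _intercept_only_model("incidence", -2.0)
        rem = _intercept_only_model("remittance", -40.0)  # p10 ~ 0
        baseline = {s: 0.1 for s in ml.DEFAULT_STRATA}
        table = build_rate_table((inc, rem), baseline, BANDS, self.reference_cohort())
        for s in ml.DEFAULT_STRATA:
            np.testing.assert_allclose(table.remittance[s], 0.0, atol=1e-12)

    def test_empty_band_is_an_error_listing_the_band(self):
        inc = _intercept_only_model("incidence", -2.0)
        rem = _intercept_only_model("remittance", -1.0)
        cohort = self.reference_cohort()
        cohort = cohort[~((cohort.age_baseline >= 33) & (cohort.age_baseline < 38))]
        baseline = {s: 0.1 for s in ml.DEFAULT_STRATA}
        with pytest.raises(EstimationError, match=r"\[33,38\)"):
            build_rate_table((inc, rem), baseline, BANDS, cohort)

    def test_joint_inversion_matches_constant_hazard_truth_exactly(self):
        # predictions generated from a known (lam, mu): inversion must return it
        lam, mu, gap = 0.12, 0.4, 3.0
        rho, pi = lam + mu, lam / (lam + mu)
        p01 = pi * (1 - np.exp(-rho * gap))
        p10 = (1 - pi) * (1 - np.exp(-rho * gap))
        inc = _intercept_only_model("incidence", np.log(p01 / (1 - p01)))
        rem = _intercept_only_model("remittance", np.log(p10 / (1 - p10)))
        baseline = {s: 0.1 for s in ml.DEFAULT_STRATA}
        table = build_rate_table(
            (inc, rem), baseline, BANDS, self.reference_cohort(gap=gap)
        )
        for s in ml.DEFAULT_STRATA:
            np.testing.assert_allclose(table.incidence[s], lam, rtol=1e-9)
            np.testing.assert_allclose(table.remittance[s], mu, rtol=1e-9)

    def test_naive_inversion_understates_incidence_under_fast_remittance(self):
        lam, mu, gap = 0.12, 0.4, 3.0
        rho, pi = lam + mu, lam / (lam + mu)
        p01 = pi * (1 - np.exp(-rho * gap))
        p10 = (1 - pi) * (1 - np.exp(-rho * gap))
        inc = _intercept_only_model("incidence", np.log(p01 / (1 - p01)))
        rem = _intercept_only_model("remittance", np.log(p10 / (1 - p10)))
        baseline = {s: 0.1 for s in ml.DEFAULT_STRATA}
        table = build_rate_table(
            (inc, rem), baseline, BANDS, self.reference_cohort(gap=gap), method="naive"
        )
        assert np.all(table.incidence[("female", 10)] < 0.8 * lam)


class TestRecovery:
    def test_five_year_band_recovery_is_unbiased_within_sampling_noise(
        self, default_specs,
    ):
        """At the default five-year resolution the estimator's band hazards
        scatter around truth within the sampling error implied by per-band
        event counts (a calibrated bound, not a fixed-percentage one)."""
        from mdd_lifecourse.cohort import recovery_config

        cfg = recovery_config(50_000, seed=915)
        frame = ml.generate_cohort(cfg)
        truth = ml.true_rate_table(cfg)
        specs = {s.name: s for s in cfg.factor_specs}
        est = ml.estimate_rate_table(frame, factor_specs=specs, stratified=False)
        rel = np.concatenate(
            [est.incidence[s] / truth.incidence[s] - 1 for s in ml.DEFAULT_STRATA]
            + [est.remittance[s] / truth.remittance[s] - 1 for s in ml.DEFAULT_STRATA]
        )
        # measured sampling SD is 3.5-5% per 5-year band (8% in the 2-year
        # band); 0.25 is ~4 SD for the weakest cell
        assert np.abs(rel).max() < 0.25
        assert np.abs(rel).mean() < 0.06

    def test_round_trip_reproduces_true_life_course_prevalence(
        self, default_cfg, default_cohort, default_specs
    ):
        """Estimate from a realistic cohort, simulate, compare with the exact
        generator truth: within 2.5 points (propagated estimation noise
        ~0.9, homogenisation bias ~0.6, Monte Carlo ~0.2)."""
        from mdd_lifecourse.cohort import true_life_course_prevalence

        est = ml.estimate_rate_table(default_cohort, factor_specs=default_specs)
        sim = ml.run_simulation(est, ml.SimulationSettings(n_per_stratum=50_000, seed=2))
        for s in ml.DEFAULT_STRATA:
            simulated = 100 * sim[s].ever_mdd.mean()
            truth = 100 * true_life_course_prevalence(default_cfg, s)
            assert abs(simulated - truth) < 2.5


class TestPPR:
    def test_equal_proportions_are_adequate_unity(self):
        r = ml.participation_prevalence_ratio(30, 100, 300, 1000)
        assert r.ratio == pytest.approx(1.0) and r.adequate

    def test_published_low_education_example(self):
        r = ml.participation_prevalence_ratio(47, 100, 50, 100)
        assert r.ratio == pytest.approx(0.94) and r.adequate

    def test_overrepresented_subgroup_flagged(self):
        r = ml.participation_prevalence_ratio(30, 100, 10, 100)
        assert r.ratio == pytest.approx(3.0) and not r.adequate

    @pytest.mark.parametrize("args", [(0, 100, 10, 100), (30, 100, 0, 100),
                                      (101, 100, 10, 100), (30.5, 100, 10, 100)])
    def test_invalid_counts_rejected(self, args):
        with pytest.raises(ValueError):
            ml.participation_prevalence_ratio(*args)
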