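# Methods

This note documents the model, the estimation pipeline, the synthetic
cohort that stands in for study data, and the numerical and design choices
behind them.

## The two-state life-course model

An adult life course between ages 18 and 65 is modelled as a
continuous-time Markov process with two states, *healthy* and *MDD*
(a current major depressive episode).  The transition intensities are
piecewise constant on age bands — by default 5-year bands anchored at 18,
with a final short band [63, 65) because 47 years is not divisible by
five:

* incidence `lam(t)`: healthy → MDD, events per person-year;
* remittance `mu(t)`: MDD → healthy.

Mortality is deliberately absent: every life course is censored at 65, so
"years with MDD" are never truncated by death.  The initial state at 18
is Bernoulli with a per-stratum prevalence.  Strata are the four
combinations of sex and education (10 = junior general secondary, "low";
16 = university, "high" — years of schooling by the fastest route).

Waiting times are sampled by exact inverse transform across band
boundaries: given uniform `u`, the next event age solves
`Lambda(t) − Lambda(a) = −ln u` with `Lambda` the cumulative hazard of the
active transition.  There is no discrete time step, hence no
discretisation bias, which makes oracle tests sharp.

The model has a closed-form occupancy probability: within a band,

    p(t) = p_eq + (p0 − p_eq) exp(−(lam+mu)(t − t0)),   p_eq = lam/(lam+mu),

chained across bands from `p(18)`.  Three exact oracles derived from it
back the test suite: the age-specific prevalence curve, the first-passage
ever-MDD probability `p18 + (1−p18)(1−exp(−∫lam))`, and the expected
total MDD years `∫ p(t) dt` (integrated analytically per band).

### Outcome definitions

* **Life-course prevalence**: share of individuals ever in the MDD state
  in [18, 65], including those already in MDD at 18.
* **Mean age of onset**: mean age of first MDD entry among individuals
  healthy at 18 who ever enter MDD.  Prevalent-at-18 cases are excluded —
  their onset age is unobserved.
* **Mean duration**: mean total years in MDD (summed across episodes,
  censored at 65) among all ever-MDD individuals, *including* those in
  MDD at 18.  The denominator choice is switchable in code; the default
  reads the duration definition literally ("among individuals who
  experienced MDD") while onset alone excludes prevalent cases.

Education gaps are oriented so that positive numbers mean a heavier
burden with low education (prevalence and duration: low − high; onset:
high − low).  Reported values are rounded half-up to one decimal;
internals keep full precision.  Age-specific prevalence is evaluated as
point-in-time state at integer ages (not interval-averaged).

### Randomness and reproducibility

Each stratum owns a Philox (counter-based) stream keyed by
`(seed, stratum index)`.  Within a stratum, the r-th draw round supplies
every individual's r-th uniform from one vector, so individual i's draw
sequence is a fixed substream independent of iteration order.  Identical
settings therefore give bit-identical life courses.

## Rate estimation from two-wave panel data

The estimation input is one record per participant: sex, education,
baseline age and MDD state, a follow-up MDD state after an irregular gap
of a few years, and nine modifiable-factor covariates.

1. **Age-18 prevalence** — logistic regression of baseline MDD on sex and
   education among participants aged ≤ 20, predicted per stratum; if the
   model is degenerate (no events, separation, rank deficiency) the
   stratum's empirical proportion is used, with a logged warning.
2. **Transition models** — logistic regressions on the two risk sets:
   baseline-healthy (outcome: MDD at follow-up) and baseline-MDD
   (outcome: remitted at follow-up).  The design matrix holds one
   indicator per age band (assigned by baseline age), `log(gap)` as an
   exposure term, and — in the pooled form — sex and centred education
   years; modifiable factors enter on request (ordinal codes, or two
   indicators for smoking never/former/current).  The default is a fully
   stratified fit (a separate model per sex × education); the pooled form
   is used wherever an education *coefficient* is needed (mediation) or
   where strata should share band-level information.
3. **Interval probabilities → hazards** — a follow-up interval can contain
   several transitions, so the observed interval probabilities are the
   two-state transition probabilities, not `1 − exp(−rate·gap)`.  The two
   directions are therefore inverted **jointly** through the closed form:

       lam + mu = −ln(1 − p01 − p10) / gap,
       lam = (lam+mu) · p01 / (p01 + p10),

   applied per covariate row with that row's gap, then averaged over the
   stratum's rows per band (marginal standardisation).  The
   single-direction inversion `−ln(1−p)/gap` is the degenerate case of
   this formula (opposing probability zero) and is available as
   `method="naive"`; under MDD-like remittance (~0.2/year) and 3-year
   gaps it understates incidence by ~20–40%, which is why the joint form
   is the default.
4. **Missing covariate cells** — single stochastic-regression imputation
   (OLS on sex, education, age; prediction plus a Gaussian residual draw,
   snapped to the nearest valid code), with a fixed seed.  This is a
   deliberately simple, replaceable placeholder for a study-specific
   missing-data procedure; the generator's missingness is MCAR, under
   which the recovery tests are unbiased.

Numerical guards: fitted log-odds above 15 in magnitude are treated as
separation and raise; unpopulated band indicators are dropped and any
later prediction into such a band raises an error naming the band;
predicted total interval probabilities are clipped just below 1.  The
inversion is ill-conditioned where `p01 + p10` approaches 1 (intervals
long relative to `1/(lam+mu)` carry almost no rate information); per-row
hazard estimates are then heavy-tailed.  Keeping follow-up gaps below
roughly `2/(lam+mu)` avoids the regime; this matters for synthetic
configurations with high rates, not for MDD-like rates.

A `participation_prevalence_ratio` helper computes the share of a
subgroup among participants relative to its population share; 0.8–1.2 is
flagged as adequate representation.

## Mediation screen and counterfactuals

The screen fits the pooled incidence model with and without a candidate
factor and reports `100·(β_total − β_adjusted)/β_total` for the education
coefficient (difference of coefficients on the log-odds scale).  The
method is deliberately the simplest defensible one — its only consumer is
the *ranking* that selects the top three factors — and is pluggable;
screening uses the incidence direction.  A total effect within tolerance
of zero raises an error (the percentage is undefined).

A counterfactual scenario replaces the low-education group's distribution
of one or more factors with the high-education group's: the swapped
factor columns of each low-education row are resampled **jointly** (whole
rows) from the high-education rows with a fixed seed, preserving the
factors' mutual correlation; all other covariates keep their observed
values; the high-education stratum and the age-18 prevalence are never
altered (a documented switch could extend the counterfactual to the
age-18 prevalence, but transition rates are the analysis's lever).
Rates are rebuilt by the same marginal standardisation and fed to the
simulator with the same seeds and sizes as baseline, so scenario
contrasts share Monte Carlo noise.  Gap reductions are
`100·(1 − counterfactual gap / baseline gap)`.

In the full-mediation limit (education acting only through the swapped
factors) the joint swap provably closes the hazard gap, which is tested;
single-factor effects need not be additive, so no additivity is asserted.

## The synthetic cohort generator

No public individual-level data exist for this design, so a generator
produces two-wave panels with known ground truth.  It emulates:
education-graded distributions of nine modifiable factors (quality of
social contacts, health literacy, smoking, partner status, physical
activity, alcohol intake, diet quality, sleep duration, network size —
ordinal risk codes, smoking as never/former/current), proportional-hazard
factor/sex/education effects on band-level rates, a baseline-MDD
logistic model, irregular follow-up gaps, and MCAR missingness.
Follow-up states come from **exact event-history simulation** of the
ground-truth process over each personal gap (multiple transitions within
the gap are possible, and exposure past age 65 keeps the last band's
hazard), so estimators must genuinely recover hazards rather than
single-jump probabilities.

Ground-truth summaries are exact: `true_rate_table` returns the
stratum-mean hazards `E[exp(factor terms)] · exp(band + sex + education)`
(the estimand of the marginal-standardisation estimator; an exp-at-mean
variant exists), and `true_life_course_prevalence` enumerates the joint
factor distribution (factors are independent given education, so the
support is an outer product) and averages the first-passage formula.

### Default study conditions

The defaults describe the population the analysis targets and were fixed
analytically, once, from published anchor quantities:

* ever-MDD by stratum ≈ 35.3 / 14.5 / 28.6 / 11.3 % (female-low,
  female-high, male-low, male-high) — inverted through the first-passage
  formula to mean incidence ≈ 0.0084 / 0.0030 / 0.0065 / 0.0023 per year;
* point prevalence < 6% at any age → mean remittance ≈ 0.18–0.27 per
  year via the equilibrium `lam/(lam+mu)`;
* incidence declining with age (profile 1.35 → 0.70 across bands),
  female/male incidence ratio ≈ 1.3, education (10 vs 16 years) rate
  ratio ≈ 2.8 of which roughly a third flows through the three main
  factors (quality of social contacts > health literacy > smoking),
  about 5% through six minor factors, the rest direct;
* age-18 prevalence ≈ 4.0 / 1.5 / 3.0 / 1.1 %;
* follow-up gaps U(2, 5) years; 5% missing factor cells; 50 000
  participants, balanced sexes and education.

Mean onset (~37) and durations (~4–6.5 years) emerge from these anchors
rather than being targeted exactly.  What passing tests under these
conditions do **not** show: robustness to informative missingness, to
attrition correlated with MDD, to measurement error in the MINI-style
binary state, to confounding of the factor–MDD association, or to
education-differential reporting — none of which the generator emulates.

### Recovery conditions

Band-level hazard recovery from a 50 000-record two-wave panel is
information-limited: the sampling SD of a band log-hazard is roughly
`sqrt(1/events) × ~1.35` (the inversion's noise amplification), i.e.
4–5% per 5-year band under event-rich conditions and far worse at
realistic MDD rates.  `recovery_config` therefore defines a separate,
openly synthetic regime for recovery studies — balanced rates
(incidence 0.15, remittance 0.25 per year), age-18 prevalence 0.45,
gaps U(2.5, 4), gentle profiles, small covariate effects — and the
band-resolution recovery check runs on a coarse 4-band partition
(18/30/42/54/65) where every band sees ~2000 transitions per direction
and a 10% accuracy budget sits ~3 standard errors above the noise.  At
the default 5-year resolution the recovery test instead uses a bound
calibrated to the measured sampling SD.  The estimate→simulate round
trip at realistic defaults is checked within 2.5 percentage points
(propagated estimation noise ~0.9, hazard-homogenisation bias ~0.6 —
the simulator runs each stratum at its mean hazard, whereas the
generator's individuals are heterogeneous — and Monte Carlo ~0.2).

## Simulation sizes

Defaults follow the headline experiment: 125 000 life courses per stratum
(500 000 total), which leaves the Monte Carlo SE of a life-course
prevalence under 0.15 percentage points (verified by replicate-seed SD,
which also scales as `1/sqrt(n)`).  The analysis drivers and the
acceptance script run the estimation-based stages at 50 000 life courses
per stratum, the package's standard size for exploratory runs; all
reported contrasts share seeds across scenarios, so scenario differences
are far more precise than levels.

## Sensitivity mode: depression history

The engine optionally switches every draw after an individual's first
remission to a second rate table.  The bundled sensitivity driver scales
estimated incidence by a recurrence multiplier (default 2) in that table.
As expected, ever-MDD prevalence is invariant (first onset precedes any
remission) while durations and episode counts rise.

## Known limitations

* The logistic-plus-inversion estimator is near the information bound but
  not a full interval-likelihood MLE; band hazards from sparse bands are
  noisy, and intervals with `p01 + p10` near 1 are uninformative.
* Band assignment by baseline age attributes exposure that crosses a band
  boundary to the baseline band; with smooth profiles and 2–5-year gaps
  the resulting bias is ~1–2%.
* The mediation screen is a difference-of-coefficients ranking, not a
  causal decomposition; non-collapsibility and mediator–outcome
  confounding are out of scope.
* Counterfactual equalisation assumes the factor–hazard association is
  transportable across education groups (no education × factor
  interaction in the models).
* No mortality, no attrition, two education levels only.
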