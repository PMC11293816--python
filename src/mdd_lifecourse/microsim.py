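"""Continuous-time two-state microsimulation of MDD life courses.

The engine simulates a healthy <-> MDD two-state Markov process on the age
axis from 18 to 65 under piecewise-constant transition hazards (incidence:
healthy -> MDD; remittance: MDD -> healthy).  Waiting times are drawn by exact
inverse-transform sampling across band boundaries, so there is no time-step
discretisation bias: given a uniform draw ``u`` the next event age solves

    Lambda(t) - Lambda(current_age) = -ln(u),

where ``Lambda`` is the cumulative hazard of the currently active transition.
Mortality is excluded by construction; every life course is censored at 65.

The same two-state process has a closed-form occupancy probability, provided
here as :func:`analytic_state_probability` and friends.  It serves as the
independent oracle for the stochastic engine: within a band with incidence
``lam`` and remittance ``mu`` the MDD-state probability follows

    p(t) = p_eq + (p0 - p_eq) * exp(-(lam + mu) * (t - t0)),
    p_eq = lam / (lam + mu),

chained across bands from p(18) = prevalence at age 18.

Randomness is counter-based (Philox): each stratum owns a keyed stream and
the r-th event draw for individual i is the i-th element of the stream's
r-th vector, so results do not depend on iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import AgeBands, END_AGE, START_AGE
from .exceptions import ConfigurationError, SimulationError
from .ratetable import DEFAULT_STRATA, RateTable, Stratum

HEALTHY = "healthy"
MDD = "mdd"

_MAX_ROUNDS = 20000


# --------------------------------------------------------------------------
# Waiting-time sampling
# --------------------------------------------------------------------------

def _cumulative_hazard_knots(hazards: np.ndarray, bands: AgeBands) -> np.ndarray:
    """Cumulative hazard from age 18 evaluated at every band boundary."""
    return np.concatenate(([0.0], np.cumsum(hazards * bands.widths)))


def _cumhaz_at(ages, hazards: np.ndarray, bands: AgeBands, knots: np.ndarray | None = None):
    """Lambda(age) for piecewise-constant hazards; vectorised."""
    if knots is None:
        knots = _cumulative_hazard_knots(hazards, bands)
    idx = bands.index_of(ages)
    return knots[idx] + (np.asarray(ages, dtype=float) - bands.starts[idx]) * hazards[idx]


def _invert_cumhaz(targets: np.ndarray, hazards: np.ndarray, bands: AgeBands,
                   knots: np.ndarray) -> np.ndarray:
    """Ages t with Lambda(t) = targets; +inf where Lambda(65) < target.

    Zero-hazard bands have zero-width cumulative-hazard intervals and are
    skipped naturally by the right-sided search.
    """
    t = np.full(targets.shape, np.inf)
    reachable = targets < knots[-1] - 1e-15
    if np.any(reachable):
        tr = targets[reachable]
        j = np.searchsorted(knots, tr, side="right") - 1
        j = np.clip(j, 0, bands.n_bands - 1)
        lam = hazards[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            ages = bands.starts[j] + (tr - knots[j]) / lam
        ages[lam == 0.0] = bands.starts[j][lam == 0.0]
        t[reachable] = ages
    return t


def sample_waiting_time(hazard_by_band, bands: AgeBands, current_age: float, u: float):
    """Age of the next transition, or ``None`` if censored at 65.

    Parameters
    ----------
    hazard_by_band:
        Piecewise-constant hazard of the active transition, one value per
        band (events/person-year).
    current_age:
        Age at which the clock starts, in [18, 65).
    u:
        A uniform(0, 1) draw; the event age solves
        ``Lambda(t) - Lambda(current_age) = -ln(u)``.
    """
    if not 0.0 < u < 1.0:
        raise ValueError(f"u must be in (0, 1), got {u}")
    if not START_AGE <= current_age < END_AGE:
        raise ValueError(f"current_age must be in [{START_AGE}, {END_AGE}), got {current_age}")
    hazards = np.asarray(hazard_by_band, dtype=float)
    if np.any(hazards < 0):
        raise ValueError("hazards must be >= 0")
    knots = _cumulative_hazard_knots(hazards, bands)
    target = _cumhaz_at(current_age, hazards, bands, knots) - np.log(u)
    t = _invert_cumhaz(np.atleast_1d(np.asarray(target, dtype=float)), hazards, bands, knots)[0]
    return None if np.isinf(t) else float(t)


# --------------------------------------------------------------------------
# Life-course containers
# --------------------------------------------------------------------------

@dataclass
class LifeCourse:
    """One simulated individual's ordered MDD state history on [18, 65]."""

    id: int
    sex: str
    education_years: int
    initial_state: str  # "healthy" | "mdd" at age 18
    transitions: list[tuple[float, str]]  # (age, new state), strictly increasing
    censor_age: float = END_AGE

    @property
    def ever_mdd(self) -> bool:
        return self.initial_state == MDD or any(s == MDD for _, s in self.transitions)

    @property
    def onset_age(self) -> float | None:
        """Age of first entry into MDD, for those healthy at 18; else None."""
        if self.initial_state == MDD:
            return None
        for age, state in self.transitions:
            if state == MDD:
                return age
        return None

    @property
    def mdd_years(self) -> float:
        """Total years spent in the MDD state (possibly across episodes)."""
        total = 0.0
        state, age = self.initial_state, START_AGE
        for t, new_state in self.transitions:
            if state == MDD:
                total += t - age
            state, age = new_state, t
        if state == MDD:
            total += self.censor_age - age
        return total

    def state_at(self, age: float) -> str:
        """Point-in-time state at ``age`` (transitions act at their age)."""
        state = self.initial_state
        for t, new_state in self.transitions:
            if t > age:
                break
            state = new_state
        return state


@dataclass
class StratumLifeCourses:
    """All simulated life courses of one stratum, stored columnar.

    ``transition_ages`` is an (n, k) float array, NaN-padded; states
    alternate deterministically starting from ``initial_mdd``.
    """

    stratum: Stratum
    initial_mdd: np.ndarray  # (n,) bool, MDD state at age 18
    transition_ages: np.ndarray  # (n, k) float, NaN padded

    def __len__(self) -> int:
        return self.initial_mdd.shape[0]

    @property
    def n_transitions(self) -> np.ndarray:
        return np.sum(~np.isnan(self.transition_ages), axis=1)

    @property
    def ever_mdd(self) -> np.ndarray:
        """True if in MDD at 18 or entering MDD at least once."""
        return self.initial_mdd | (self.n_transitions > 0)

    @property
    def onset_age(self) -> np.ndarray:
        """First MDD entry age among the initially healthy; NaN otherwise."""
        onset = np.full(len(self), np.nan)
        healthy0 = ~self.initial_mdd
        if self.transition_ages.shape[1] > 0:
            onset[healthy0] = self.transition_ages[healthy0, 0]
        return onset

    @property
    def mdd_years(self) -> np.ndarray:
        """Total MDD-state years per individual, censored at 65."""
        n, k = self.transition_ages.shape
        filled = np.nan_to_num(self.transition_ages, nan=END_AGE)
        knots = np.column_stack([np.full(n, START_AGE), filled, np.full(n, END_AGE)])
        seg = np.diff(knots, axis=1)  # (n, k+1); segment j precedes transition j
        parity = np.arange(k + 1) % 2 == 1  # segment j is in the non-initial state iff j odd
        in_mdd = np.where(self.initial_mdd[:, None], ~parity[None, :], parity[None, :])
        return np.sum(seg * in_mdd, axis=1)

    def state_at(self, age: float) -> np.ndarray:
        """Boolean MDD indicator per individual at a point age."""
        counts = np.sum(self.transition_ages <= age, axis=1)
        return self.initial_mdd ^ (counts % 2 == 1)

    def prevalence_curve(self, ages=None) -> np.ndarray:
        """Point-in-time MDD prevalence at each requested age (default 18..65)."""
        if ages is None:
            ages = np.arange(START_AGE, END_AGE + 1)
        return np.array([self.state_at(a).mean() for a in np.asarray(ages, dtype=float)])

    def __getitem__(self, i: int) -> LifeCourse:
        ages = self.transition_ages[i]
        ages = ages[~np.isnan(ages)]
        state0 = MDD if self.initial_mdd[i] else HEALTHY
        states = [HEALTHY, MDD] if self.initial_mdd[i] else [MDD, HEALTHY]
        transitions = [(float(a), states[j % 2]) for j, a in enumerate(ages)]
        return LifeCourse(
            id=i,
            sex=self.stratum[0],
            education_years=self.stratum[1],
            initial_state=state0,
            transitions=transitions,
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def to_frame(self) -> pd.DataFrame:  # noqa: F821 - imported lazily below
        """Long-format event-history frame (id, sex, education, age, state)."""
        import pandas as pd

        rows = []
        for lc in self:
            rows.append((lc.id, lc.sex, lc.education_years, START_AGE, lc.initial_state))
            for age, state in lc.transitions:
                rows.append((lc.id, lc.sex, lc.education_years, age, state))
        return pd.DataFrame(rows, columns=["id", "sex", "education_years", "age", "state"])


# --------------------------------------------------------------------------
# Settings
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationSettings:
    """How many life courses to simulate, and under which seed.

    The default reproduces the headline experiment: 125 000 life courses in
    each of the four sex x education strata (500 000 total).
    """

    n_per_stratum: int = 125_000
    seed: int = 0
    strata: tuple[Stratum, ...] = DEFAULT_STRATA

    def __post_init__(self) -> None:
        if self.n_per_stratum <= 0:
            raise ConfigurationError("n_per_stratum: must be > 0")
        if not self.strata:
            raise ConfigurationError("strata: must be non-empty")

    def replicate(self, index: int) -> "SimulationSettings":
        """Settings for an independent Monte Carlo replicate."""
        child = int(np.random.SeedSequence([self.seed, index]).generate_state(1)[0] % 2**31)
        return SimulationSettings(self.n_per_stratum, child, self.strata)


# --------------------------------------------------------------------------
# Engine
# --------------------------------------------------------------------------

def _stratum_rng(seed: int, stratum_index: int) -> np.random.Generator:
    # Philox is counter-based; keying by (seed, stratum) gives independent
    # streams whose r-th vector supplies every individual's r-th draw.
    return np.random.Generator(np.random.Philox(key=(int(seed) << 32) + stratum_index))


def simulate_two_state(
    inc_bands: np.ndarray,
    rem_bands: np.ndarray,
    bands: AgeBands,
    initial_mdd: np.ndarray,
    start_age,
    end_age,
    rng: np.random.Generator,
    m_inc: np.ndarray | None = None,
    m_rem: np.ndarray | None = None,
    hist_inc: np.ndarray | None = None,
    hist_rem: np.ndarray | None = None,
    record_transitions: bool = True,
):
    """Vectorised exact simulation of the two-state process for n individuals.

    Individuals share the band-level hazard profiles ``inc_bands`` and
    ``rem_bands`` up to optional per-individual multipliers ``m_inc`` and
    ``m_rem`` (proportional-hazards heterogeneity).  If history profiles are
    given, every draw after an individual's first remission uses them
    instead (the depression-history sensitivity mode).

    Returns ``(final_mdd, transition_ages)`` where ``transition_ages`` is the
    NaN-padded (n, k) event-age matrix (``None`` when not recorded).
    """
    n = initial_mdd.shape[0]
    start_age = np.broadcast_to(np.asarray(start_age, dtype=float), (n,)).copy()
    end_age = np.broadcast_to(np.asarray(end_age, dtype=float), (n,)).copy()
    state = initial_mdd.copy()
    remitted_once = np.zeros(n, dtype=bool)
    age = start_age
    active = age < end_age
    columns: list[np.ndarray] = []

    profiles = {
        (True, False): np.asarray(rem_bands, dtype=float),
        (False, False): np.asarray(inc_bands, dtype=float),
        (True, True): np.asarray(hist_rem if hist_rem is not None else rem_bands, dtype=float),
        (False, True): np.asarray(hist_inc if hist_inc is not None else inc_bands, dtype=float),
    }
    knots = {key: _cumulative_hazard_knots(h, bands) for key, h in profiles.items()}
    mult = {True: m_rem, False: m_inc}

    rounds = 0
    while np.any(active):
        rounds += 1
        if rounds > _MAX_ROUNDS:
            raise SimulationError("transition count exceeded the engine's round cap")
        u = rng.random(n)  # full vector: individual i always owns slot i
        t_event = np.full(n, np.inf)
        for key, hazards in profiles.items():
            in_state, with_hist = key
            mask = active & (state == in_state) & (remitted_once == with_hist)
            if not np.any(mask):
                continue
            targets = -np.log(u[mask])
            m = mult[in_state]
            if m is not None:
                targets = targets / m[mask]
            targets = targets + _cumhaz_at(age[mask], hazards, bands, knots[key])
            t_event[mask] = _invert_cumhaz(targets, hazards, bands, knots[key])
        happened = active & (t_event < end_age)
        active = happened.copy()
        if not np.any(happened):
            break
        if record_transitions:
            col = np.full(n, np.nan)
            col[happened] = t_event[happened]
            columns.append(col)
        # a True->False flip is a remission
        remitted_once[happened & state] = True
        state[happened] = ~state[happened]
        age = np.where(happened, t_event, age)

    transitions = (
        np.column_stack(columns) if columns else np.empty((n, 0))
    ) if record_transitions else None
    return state, transitions


def simulate_life_course(
    rates: RateTable,
    stratum: Stratum,
    rng: np.random.Generator,
    history_rates: RateTable | None = None,
    id: int = 0,
) -> LifeCourse:
    """Simulate a single life course (scalar reference implementation).

    The initial state is Bernoulli(prevalence at 18); the process then
    alternates incidence and remittance waiting-time draws until censoring
    at 65.  After the first remission, draws switch to ``history_rates``
    when provided.
    """
    if not rates.has_stratum(stratum):
        raise SimulationError(f"rate table does not cover stratum {stratum}")
    if history_rates is not None and not history_rates.has_stratum(stratum):
        raise SimulationError(f"history rate table does not cover stratum {stratum}")
    bands = rates.bands
    in_mdd = bool(rng.random() < rates.prevalence_at_18[stratum])
    initial = MDD if in_mdd else HEALTHY
    transitions: list[tuple[float, str]] = []
    age, remitted = START_AGE, False
    while age < END_AGE:
        table = history_rates if (remitted and history_rates is not None) else rates
        hazards = table.remittance[stratum] if in_mdd else table.incidence[stratum]
        t = sample_waiting_time(hazards, bands, age, rng.random())
        if t is None:
            break
        if in_mdd:
            remitted = True
        in_mdd = not in_mdd
        transitions.append((t, MDD if in_mdd else HEALTHY))
        age = t
    return LifeCourse(id, stratum[0], stratum[1], initial, transitions)


def run_simulation(
    rates: RateTable,
    settings: SimulationSettings,
    history_rates: RateTable | None = None,
) -> dict[Stratum, StratumLifeCourses]:
    """Simulate ``settings.n_per_stratum`` life courses per stratum.

    Deterministic given the seed: each stratum has its own Philox stream
    keyed by (seed, stratum index).
    """
    out: dict[Stratum, StratumLifeCourses] = {}
    for k, stratum in enumerate(settings.strata):
        if not rates.has_stratum(stratum):
            raise SimulationError(f"rate table does not cover stratum {stratum}")
        if history_rates is not None and not history_rates.has_stratum(stratum):
            raise SimulationError(f"history rate table does not cover stratum {stratum}")
        rng = _stratum_rng(settings.seed, k)
        n = settings.n_per_stratum
        initial_mdd = rng.random(n) < rates.prevalence_at_18[stratum]
        _, transitions = simulate_two_state(
            rates.incidence[stratum],
            rates.remittance[stratum],
            rates.bands,
            initial_mdd,
            START_AGE,
            END_AGE,
            rng,
            hist_inc=history_rates.incidence[stratum] if history_rates is not None else None,
            hist_rem=history_rates.remittance[stratum] if history_rates is not None else None,
        )
        out[stratum] = StratumLifeCourses(stratum, initial_mdd, transitions)
    return out


# --------------------------------------------------------------------------
# Closed-form oracles
# --------------------------------------------------------------------------

def analytic_state_probability(rates: RateTable, stratum: Stratum, age: float) -> float:
    """Closed-form P(in MDD state at ``age``) for the two-state process.

    Solves p' = lam(t) (1 - p) - mu(t) p band by band from
    p(18) = prevalence_at_18.  A band with lam + mu = 0 keeps p constant.
    """
    return float(analytic_prevalence_curve(rates, stratum, [age])[0])


def analytic_prevalence_curve(rates: RateTable, stratum: Stratum, ages) -> np.ndarray:
    """Vectorised :func:`analytic_state_probability` over many ages."""
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < START_AGE) or np.any(ages > END_AGE):
        raise ValueError(f"ages must lie in [{START_AGE}, {END_AGE}]")
    if not rates.has_stratum(stratum):
        raise SimulationError(f"rate table does not cover stratum {stratum}")
    bands = rates.bands
    lam_all = rates.incidence[stratum]
    mu_all = rates.remittance[stratum]
    out = np.empty(ages.shape)
    p0 = rates.prevalence_at_18[stratum]
    p_at_start = {0: p0}
    # p at the start of every band, chained with the within-band closed form
    for b in range(bands.n_bands):
        p_at_start[b + 1] = _band_solution(
            p_at_start[b], lam_all[b], mu_all[b], bands.widths[b]
        )
    idx = bands.index_of(ages)
    for i, (a, b) in enumerate(zip(ages, idx)):
        out[i] = _band_solution(p_at_start[b], lam_all[b], mu_all[b], a - bands.starts[b])
    return out


def _band_solution(p0: float, lam: float, mu: float, dt: float) -> float:
    rho = lam + mu
    if rho == 0.0:
        return p0
    p_eq = lam / rho
    return p_eq + (p0 - p_eq) * np.exp(-rho * dt)


def cumulative_incidence_hazard(rates: RateTable, stratum: Stratum, age: float = END_AGE) -> float:
    """Integral of the incidence hazard from 18 to ``age``."""
    bands = rates.bands
    knots = _cumulative_hazard_knots(rates.incidence[stratum], bands)
    return float(_cumhaz_at(age, rates.incidence[stratum], bands, knots))


def first_passage_mdd_probability(rates: RateTable, stratum: Stratum,
                                  age: float = END_AGE) -> float:
    """P(ever in MDD by ``age``) = p18 + (1 - p18) (1 - exp(-Lambda_inc)).

    First entry into MDD depends on the incidence hazard only, so the
    ever-MDD probability has this exact first-passage form.
    """
    p18 = rates.prevalence_at_18[stratum]
    lam = cumulative_incidence_hazard(rates, stratum, age)
    return float(p18 + (1.0 - p18) * (1.0 - np.exp(-lam)))


def expected_mdd_years(rates: RateTable, stratum: Stratum) -> float:
    """E[total MDD years over 18-65] = integral of p(t); exact per band.

    Within a band, integral of p is ``p_eq dt + (p0 - p_eq)(1 - e^{-rho dt})/rho``.
    """
    bands = rates.bands
    lam_all, mu_all = rates.incidence[stratum], rates.remittance[stratum]
    p = rates.prevalence_at_18[stratum]
    total = 0.0
    for b in range(bands.n_bands):
        lam, mu, dt = lam_all[b], mu_all[b], bands.widths[b]
        rho = lam + mu
        if rho == 0.0:
            total += p * dt
        else:
            p_eq = lam / rho
            total += p_eq * dt + (p - p_eq) * (1.0 - np.exp(-rho * dt)) / rho
        p = _band_solution(p, lam, mu, dt)
    return float(total)
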