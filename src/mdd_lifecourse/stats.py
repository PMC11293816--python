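"""Life-course outcome statistics and inequality gap arithmetic.

Outcome definitions:

* **Life-course prevalence** — percentage of individuals ever in the MDD
  state between 18 and 65 (including those already in MDD at 18).
* **Mean age of onset** — average age of first MDD entry among individuals
  healthy at 18 who ever develop MDD (prevalent-at-18 cases excluded).
* **Mean duration** — average total years in the MDD state (summed across
  episodes, censored at 65) among all ever-MDD individuals, including
  those starting in MDD.

Education gaps are oriented so positive values mean a heavier burden for
the low-education group: prevalence and duration gaps are low minus high,
the onset gap is high minus low (positive = earlier onset with low
education).  Reported values are rounded half-up to one decimal; internal
values keep full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import END_AGE, START_AGE
from .exceptions import ConfigurationError
from .microsim import RateTable, SimulationSettings, StratumLifeCourses, run_simulation
from .ratetable import Stratum

OUTCOMES = ("prevalence", "onset", "duration")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties going up (0.85 -> 0.9), as in reporting.

    The scaled value is first snapped to 8 decimals so that a tie computed
    in floating point (e.g. a mean of two one-decimal values, 19.049999...)
    is recognised as the tie it analytically is.
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    factor = 10 ** decimals
    return math.floor(round(x * factor, 8) + 0.5) / factor


@dataclass
class LifeCourseSummary:
    """Per-stratum life-course outcome statistics."""

    stratum: Stratum
    n: int
    life_course_prevalence: float  # percent ever in MDD
    mean_age_onset: float          # NaN when no qualifying onsets
    mean_duration: float           # NaN when nobody was ever in MDD
    age_specific_prevalence: np.ndarray = field(repr=False)  # per integer age 18..65
    ages: np.ndarray = field(default_factory=lambda: np.arange(START_AGE, END_AGE + 1),
                             repr=False)

    @property
    def onset_defined(self) -> bool:
        return not math.isnan(self.mean_age_onset)

    @property
    def duration_defined(self) -> bool:
        return not math.isnan(self.mean_duration)

    def rounded(self) -> dict:
        return dict(
            stratum=self.stratum,
            life_course_prevalence=round_half_up(self.life_course_prevalence),
            mean_age_onset=round_half_up(self.mean_age_onset),
            mean_duration=round_half_up(self.mean_duration),
        )


def summarize(lifecourses: StratumLifeCourses) -> LifeCourseSummary:
    """Life-course prevalence, onset, duration and the prevalence curve."""
    n = len(lifecourses)
    if n == 0:
        raise ConfigurationError("summarize: empty stratum")
    ever = lifecourses.ever_mdd
    prevalence = 100.0 * float(ever.mean())
    onset = lifecourses.onset_age
    onset = onset[~np.isnan(onset)]
    mean_onset = float(onset.mean()) if onset.size else float("nan")
    durations = lifecourses.mdd_years[ever]
    mean_duration = float(durations.mean()) if durations.size else float("nan")
    curve = lifecourses.prevalence_curve()
    return LifeCourseSummary(
        stratum=lifecourses.stratum,
        n=n,
        life_course_prevalence=prevalence,
        mean_age_onset=mean_onset,
        mean_duration=mean_duration,
        age_specific_prevalence=curve,
    )


def summaries_to_frame(summaries: dict) -> pd.DataFrame:
    rows = []
    for (sex, edu), s in summaries.items():
        rows.append(
            dict(
                sex=sex,
                education_years=edu,
                n=s.n,
                life_course_prevalence=s.life_course_prevalence,
                mean_age_onset=s.mean_age_onset,
                mean_duration=s.mean_duration,
            )
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Gaps, reductions, pooling
# --------------------------------------------------------------------------

def inequality_gaps(low: LifeCourseSummary, high: LifeCourseSummary) -> dict[str, float]:
    """Education gaps per outcome for one sex (positive = low-education burden).

    Undefined components (NaN onsets/durations) propagate as NaN gaps.
    """
    if low.stratum[0] != high.stratum[0]:
        raise ConfigurationError("inequality_gaps: summaries must share the same sex")
    return {
        "prevalence": low.life_course_prevalence - high.life_course_prevalence,
        "onset": high.mean_age_onset - low.mean_age_onset,
        "duration": low.mean_duration - high.mean_duration,
    }


def gap_reduction(baseline_gap: float, counterfactual_gap: float) -> float:
    """Percentage by which a counterfactual shrinks an inequality gap."""
    if baseline_gap == 0 or math.isnan(baseline_gap):
        raise ConfigurationError("gap_reduction: baseline gap is zero or undefined")
    return 100.0 * (1.0 - counterfactual_gap / baseline_gap)


def pooled_summary(female, male):
    """Unweighted mean over the sexes (valid because strata are evenly sized).

    Accepts two floats, two per-outcome dicts (pooled elementwise) or two
    :class:`LifeCourseSummary` objects with equal ``n``.
    """
    if isinstance(female, LifeCourseSummary) and isinstance(male, LifeCourseSummary):
        if female.n != male.n:
            raise ConfigurationError(
                "pooled_summary: unequal stratum sizes; supply explicit weights instead"
            )
        return {
            "prevalence": (female.life_course_prevalence + male.life_course_prevalence) / 2.0,
            "onset": (female.mean_age_onset + male.mean_age_onset) / 2.0,
            "duration": (female.mean_duration + male.mean_duration) / 2.0,
        }
    if isinstance(female, dict) and isinstance(male, dict):
        return {k: (female[k] + male[k]) / 2.0 for k in female}
    return (float(female) + float(male)) / 2.0


@dataclass(frozen=True)
class ScenarioResult:
    """Baseline vs counterfactual gap for one outcome and sex."""

    outcome: str
    sex: str
    baseline_gap: float
    counterfactual_gap: float
    reduction: float  # percent, 100 * (1 - counterfactual/baseline)


def scenario_results(baseline_summaries: dict, counterfactual_summaries: dict
                     ) -> list[ScenarioResult]:
    """Per-outcome, per-sex gap reductions of one counterfactual scenario."""
    out = []
    for sex in ("female", "male"):
        base = inequality_gaps(baseline_summaries[(sex, 10)], baseline_summaries[(sex, 16)])
        cf = inequality_gaps(
            counterfactual_summaries[(sex, 10)], counterfactual_summaries[(sex, 16)]
        )
        for outcome in OUTCOMES:
            out.append(
                ScenarioResult(
                    outcome=outcome,
                    sex=sex,
                    baseline_gap=base[outcome],
                    counterfactual_gap=cf[outcome],
                    reduction=gap_reduction(base[outcome], cf[outcome]),
                )
            )
    return out


def scenario_results_to_frame(results_by_scenario: dict[str, list[ScenarioResult]]
                              ) -> pd.DataFrame:
    rows = []
    for name, results in results_by_scenario.items():
        for r in results:
            rows.append(
                dict(
                    scenario=name, outcome=r.outcome, sex=r.sex,
                    baseline_gap=r.baseline_gap, counterfactual_gap=r.counterfactual_gap,
                    reduction=r.reduction,
                )
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Monte Carlo uncertainty
# --------------------------------------------------------------------------

def monte_carlo_se(
    rates: RateTable,
    settings: SimulationSettings,
    n_replicates: int,
    statistic,
) -> float:
    """SD of ``statistic(summaries)`` across independent-seed replicates.

    ``statistic`` receives the per-stratum summary mapping of one replicate
    and returns a float.
    """
    if n_replicates < 2:
        raise ConfigurationError("monte_carlo_se: need at least 2 replicates")
    values = []
    for r in range(n_replicates):
        courses = run_simulation(rates, settings.replicate(r))
        summaries = {stratum: summarize(slc) for stratum, slc in courses.items()}
        values.append(float(statistic(summaries)))
    return float(np.std(values, ddof=1))


# --------------------------------------------------------------------------
# Plotting
# --------------------------------------------------------------------------

def plot_prevalence_curves(summaries: dict, path, analytic: dict | None = None) -> None:
    """Age-specific MDD prevalence per stratum (optionally with the
    closed-form curves overlaid), written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    styles = {10: "-", 16: "--"}
    colors = {"female": "tab:red", "male": "tab:blue"}
    for (sex, edu), s in summaries.items():
        label = f"{sex}, {'low' if edu == 10 else 'high'} education"
        ax.plot(s.ages, 100 * s.age_specific_prevalence, styles[edu],
                color=colors[sex], label=label)
        if analytic is not None and (sex, edu) in analytic:
            ax.plot(s.ages, 100 * np.asarray(analytic[(sex, edu)]), ":",
                    color="black", linewidth=0.8)
    ax.set_xlabel("Age (years)")
    ax.set_ylabel("MDD prevalence (%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
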