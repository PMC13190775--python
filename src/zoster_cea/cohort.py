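"""Annual-cycle Markov cohort engine.

One :func:`run_cohort` call follows a single age-sex cohort through annual
cycles from its start age to the model's maximum age (105).  Within a cycle
the order of events is: deaths first, then HZ episodes among survivors.
Episodes are expectations, not sampled counts; each incident episode is
charged its full expected QALY loss and cost in the onset cycle (the HZ and
PHN tunnel states are sub-annual in spirit, so pain months that overrun the
cycle are not carried over).  Survivors accrue their baseline utility each
cycle.  Cycle ``t`` is discounted by ``(1 + r)^-(t - 1)``: the first year
is undiscounted.

Recurrence is permitted every cycle at the incident rate, so lifetime
episode counts can exceed the number of persons ever affected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .parameters import (
    HZ_CATEGORIES,
    PAIN_STATES,
    ParameterError,
    ParameterSet,
)
from .protection import ProtectionProfile

__all__ = [
    "ARMS",
    "START_AGES",
    "CohortSpec",
    "EpisodeOutcome",
    "CohortTrace",
    "episode_qaly_loss",
    "episode_cost",
    "episode_outcome",
    "run_cohort",
]

ARMS = ("no_vaccination", "rzv")
START_AGES = (65, 70, 75, 80, 85, 90, 95, 100)


@dataclass(frozen=True)
class CohortSpec:
    """One age-sex cohort in one comparison arm."""

    start_age: int
    sex: str
    size: float
    arm: str

    def __post_init__(self) -> None:
        if self.start_age not in START_AGES:
            raise ParameterError(
                f"start_age must be one of {START_AGES}, got {self.start_age}"
            )
        if self.sex not in ("female", "male"):
            raise ParameterError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.size <= 0:
            raise ParameterError(f"cohort size must be > 0, got {self.size}")
        if self.arm not in ARMS:
            raise ParameterError(f"arm must be one of {ARMS}, got {self.arm!r}")


@dataclass(frozen=True)
class EpisodeOutcome:
    """Expected consequences of one HZ episode at a given age and sex."""

    qaly_loss: float
    visit_cost: float
    medication_cost: float

    @property
    def cost(self) -> float:
        return self.visit_cost + self.medication_cost


def episode_qaly_loss(age: int, sex: str, params: ParameterSet) -> float:
    """Expected QALY loss per incident HZ episode.

    The acute month applies the age-group severity mix to everyone; PHN
    cases additionally lose utility over the severity-specific PHN duration.
    A pain state retains fraction ``m(s)`` of the baseline utility, so the
    per-month decrement is ``u * (1 - m(s)) / 12``; individuals return to
    baseline immediately after the pain episode.
    """
    epi, util = params.epidemiology, params.utilities
    u = util.baseline_utility(age, sex)
    dur = epi.duration_months
    acute = (
        sum(p * (1.0 - util.multiplier(s)) for s, p in epi.hz_severity(age).items())
        * u
        * dur["hz"]
        / 12.0
    )
    phn = (
        epi.phn_mean(age)
        * u
        * sum(
            epi.phn_pain_severity[s] * (1.0 - util.multiplier(s)) * dur[s] / 12.0
            for s in PAIN_STATES
        )
    )
    return acute + phn


def _episode_cost_parts(age: int, params: ParameterSet):
    epi, ut, c = params.epidemiology, params.utilization, params.costs
    visit_cost = sum(
        ut.category_mix[k]
        * (
            ut.visits[k]["primary"] * c.primary_care_visit
            + ut.visits[k]["outpatient"] * c.outpatient_visit[k]
            + ut.visits[k]["inpatient"] * c.inpatient_episode
        )
        for k in HZ_CATEGORIES
    )
    antiviral = (
        sum(ut.category_mix[k] * ut.uptake(k, "antivirals") for k in HZ_CATEGORIES)
        * c.antiviral_course
    )
    p_phn = epi.phn_mean(age)
    expected_months = (1.0 - p_phn) * epi.duration_months["hz"] + p_phn * epi.expected_phn_months()
    analgesic = (
        sum(ut.category_mix[k] * ut.uptake(k, "analgesics") for k in HZ_CATEGORIES)
        * c.analgesic_per_month
        * expected_months
    )
    return visit_cost, antiviral + analgesic


def episode_cost(age: int, sex: str, params: ParameterSet) -> float:
    """Expected direct cost (EUR) per incident HZ episode.

    Visit costs mix the five ICD-10 categories by the configured category
    shares; medication adds the antiviral course for treated cases and
    analgesics over the expected months of pain (the acute month mixed with
    the PHN durations by PHN probability).
    """
    visit, medication = _episode_cost_parts(age, params)
    return visit + medication


def episode_outcome(age: int, sex: str, params: ParameterSet) -> EpisodeOutcome:
    visit, medication = _episode_cost_parts(age, params)
    return EpisodeOutcome(
        qaly_loss=episode_qaly_loss(age, sex, params),
        visit_cost=visit,
        medication_cost=medication,
    )


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancies, events, QALYs and costs for one cohort arm.

    All arrays are indexed by cycle (cycle 1 first).  Monetary and QALY
    arrays are undiscounted; ``discount_factors`` converts them, and the
    ``*_discounted`` properties and totals do so on demand.
    """

    spec: CohortSpec
    ages: np.ndarray
    alive: np.ndarray  # persons alive at cycle start
    deaths: np.ndarray
    episodes: np.ndarray  # incident HZ episodes (expected)
    phn_cases: np.ndarray
    excess_strokes: np.ndarray
    qalys: np.ndarray
    vaccination_costs: np.ndarray
    visit_costs: np.ndarray
    medication_costs: np.ndarray
    stroke_costs: np.ndarray
    discount_factors: np.ndarray

    # -- per-cycle discounted views ---------------------------------------

    @property
    def qalys_discounted(self) -> np.ndarray:
        return self.qalys * self.discount_factors

    @property
    def hz_costs(self) -> np.ndarray:
        return self.visit_costs + self.medication_costs + self.stroke_costs

    @property
    def hz_costs_discounted(self) -> np.ndarray:
        return self.hz_costs * self.discount_factors

    @property
    def vaccination_costs_discounted(self) -> np.ndarray:
        return self.vaccination_costs * self.discount_factors

    @property
    def costs(self) -> np.ndarray:
        return self.hz_costs + self.vaccination_costs

    @property
    def costs_discounted(self) -> np.ndarray:
        return self.costs * self.discount_factors

    # -- totals ------------------------------------------------------------

    @property
    def total_episodes(self) -> float:
        return float(self.episodes.sum())

    @property
    def total_phn_cases(self) -> float:
        return float(self.phn_cases.sum())

    @property
    def total_qalys_discounted(self) -> float:
        return float(self.qalys_discounted.sum())

    @property
    def total_hz_cost_discounted(self) -> float:
        return float(self.hz_costs_discounted.sum())

    @property
    def total_vaccination_cost_discounted(self) -> float:
        return float(self.vaccination_costs_discounted.sum())

    @property
    def total_cost_discounted(self) -> float:
        return float(self.costs_discounted.sum())

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-cycle table (one row per cycle)."""
        t = np.arange(1, len(self.ages) + 1)
        return pd.DataFrame(
            {
                "cycle": t,
                "age": self.ages,
                "sex": self.spec.sex,
                "arm": self.spec.arm,
                "alive": self.alive,
                "deaths": self.deaths,
                "hz_episodes": self.episodes,
                "phn_cases": self.phn_cases,
                "excess_strokes": self.excess_strokes,
                "qalys": self.qalys,
                "qalys_discounted": self.qalys_discounted,
                "vaccination_costs": self.vaccination_costs,
                "visit_costs": self.visit_costs,
                "medication_costs": self.medication_costs,
                "stroke_costs": self.stroke_costs,
                "costs_discounted": self.costs_discounted,
                "discount_factor": self.discount_factors,
            }
        )

    def pathway_breakdown(self, params: ParameterSet) -> pd.DataFrame:
        """Episodes split by category x PHN status (deterministic shares)."""
        rows = []
        epi, ut = params.epidemiology, params.utilization
        for i, age in enumerate(self.ages):
            p_phn = epi.phn_mean(int(age))
            for cat in HZ_CATEGORIES:
                share = ut.category_mix[cat]
                for phn_flag, w in (("phn", p_phn), ("no_phn", 1.0 - p_phn)):
                    rows.append(
                        {
                            "cycle": i + 1,
                            "age": int(age),
                            "category": cat,
                            "phn": phn_flag,
                            "episodes": float(self.episodes[i] * share * w),
                        }
                    )
        return pd.DataFrame(rows)


def run_cohort(
    spec: CohortSpec,
    params: ParameterSet,
    protection: Optional[ProtectionProfile] = None,
) -> CohortTrace:
    """Run the deterministic (expectation) cohort model for one arm.

    The vaccinated arm requires a :class:`ProtectionProfile` whose horizon
    covers every cycle; vaccination costs (doses at price plus
    administration) are charged in cycle 1.
    """
    econ = params.economics
    n_cycles = econ.max_age - spec.start_age + 1
    if spec.arm == "rzv":
        if protection is None:
            raise ParameterError("the rzv arm requires a protection profile")
        if len(protection) < n_cycles:
            raise ParameterError(
                f"protection horizon {len(protection)} shorter than the "
                f"{n_cycles} model cycles"
            )
        mult = np.array([protection.multiplier(t) for t in range(1, n_cycles + 1)])
    else:
        mult = np.ones(n_cycles)

    ages = spec.start_age + np.arange(n_cycles)
    dem, epi, util = params.demography, params.epidemiology, params.utilities
    q = np.array([dem.death_prob(a, spec.sex) for a in ages])
    inc = np.array([epi.incidence(a, spec.sex) for a in ages])
    u_base = np.array([util.baseline_utility(a, spec.sex) for a in ages])
    p_phn = np.array([epi.phn_mean(a) for a in ages])
    outcomes = [episode_outcome(a, spec.sex, params) for a in ages]
    loss = np.array([o.qaly_loss for o in outcomes])
    visit = np.array([o.visit_cost for o in outcomes])
    medication = np.array([o.medication_cost for o in outcomes])

    survivors = spec.size * np.cumprod(1.0 - q)
    alive = np.concatenate(([spec.size], survivors[:-1]))
    deaths = alive - survivors
    episodes = survivors * inc * mult
    phn_cases = episodes * p_phn
    qalys = survivors * u_base - episodes * loss

    stroke = params.stroke
    if stroke.enabled:
        base_stroke = np.array([stroke.incidence(a, spec.sex) for a in ages])
        excess = episodes * (stroke.relative_risk_first_year - 1.0) * base_stroke
        stroke_costs = excess * stroke.cost_per_stroke
        qalys = qalys - excess * u_base * (1.0 - stroke.utility_multiplier_first_year)
    else:
        excess = np.zeros(n_cycles)
        stroke_costs = np.zeros(n_cycles)

    vaccination = np.zeros(n_cycles)
    if spec.arm == "rzv":
        prog, costs = params.program, params.costs
        doses = spec.size * prog.coverage * prog.doses_per_first_dose_recipient
        vaccination[0] = doses * (costs.vaccine_price_per_dose + costs.administration_per_dose)

    discount = (1.0 + econ.discount_rate) ** (-np.arange(n_cycles, dtype=float))

    return CohortTrace(
        spec=spec,
        ages=ages,
        alive=alive,
        deaths=deaths,
        episodes=episodes,
        phn_cases=phn_cases,
        excess_strokes=excess,
        qalys=qalys,
        vaccination_costs=vaccination,
        visit_costs=episodes * visit,
        medication_costs=episodes * medication,
        stroke_costs=stroke_costs,
        discount_factors=discount,
    )
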