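"""Per-person microsimulation oracle for the cohort expectation engine.

Independent of the matrix/expectation code path: individuals are simulated
one by one (vectorised across persons), with deaths, HZ episodes, pathway
(category, PHN, severities) and medication uptake all drawn as Bernoulli /
categorical samples.  Expected totals from the deterministic engine must
agree with the sample means within Monte-Carlo error.
"""

from __future__ import annotations

import numpy as np

from zoster_cea.parameters import (
    HZ_CATEGORIES,
    PAIN_STATES,
    SEVERITIES,
    ParameterSet,
)


def microsimulate(
    params: ParameterSet,
    start_age: int,
    sex: str,
    size: float,
    multipliers,
    n_persons: int,
    rng: np.random.Generator,
) -> dict:
    """Simulate ``n_persons`` individuals; scale totals to a ``size`` cohort.

    ``multipliers`` is the per-year incidence multiplier sequence for the
    arm (``None`` for no vaccination).  Returns ``{quantity: (total, se)}``
    for episodes, PHN cases, discounted QALYs and discounted HZ costs.
    """
    econ = params.economics
    n_cycles = econ.max_age - start_age + 1
    mult = np.ones(n_cycles) if multipliers is None else np.asarray(multipliers[:n_cycles])
    epi, util, ut, costs = (
        params.epidemiology,
        params.utilities,
        params.utilization,
        params.costs,
    )
    disc = (1.0 + econ.discount_rate) ** (-np.arange(n_cycles, dtype=float))

    cats = list(HZ_CATEGORIES)
    mix = np.array([ut.category_mix[k] for k in cats])
    visit_cost = np.array(
        [
            ut.visits[k]["primary"] * costs.primary_care_visit
            + ut.visits[k]["outpatient"] * costs.outpatient_visit[k]
            + ut.visits[k]["inpatient"] * costs.inpatient_episode
            for k in cats
        ]
    )
    antiviral_uptake = np.array([ut.uptake(k, "antivirals") for k in cats])
    analgesic_uptake = np.array([ut.uptake(k, "analgesics") for k in cats])
    phn_probs = np.array([epi.phn_pain_severity[s] for s in PAIN_STATES])
    phn_durations = np.array([epi.duration_months[s] for s in PAIN_STATES])
    phn_mult = np.array([util.multiplier(s) for s in PAIN_STATES])

    alive = np.ones(n_persons, dtype=bool)
    qalys = np.zeros(n_persons)
    cost = np.zeros(n_persons)
    episodes = np.zeros(n_persons)
    phn_cases = np.zeros(n_persons)

    for t in range(n_cycles):
        age = start_age + t
        q = params.demography.death_prob(age, sex)
        inc = epi.incidence(age, sex) * mult[t]
        u = util.baseline_utility(age, sex)

        alive &= rng.random(n_persons) >= q  # deaths first
        qalys[alive] += u * disc[t]

        hz = alive & (rng.random(n_persons) < inc)
        idx = np.flatnonzero(hz)
        if idx.size == 0:
            continue
        episodes[idx] += 1.0

        sev_row = epi.hz_severity(age)
        acute_mult = np.array([util.multiplier(s) for s in SEVERITIES])[
            rng.choice(len(SEVERITIES), size=idx.size, p=[sev_row[s] for s in SEVERITIES])
        ]
        loss = u * (1.0 - acute_mult) * epi.duration_months["hz"] / 12.0

        has_phn = rng.random(idx.size) < epi.phn_mean(age)
        phn_cases[idx] += has_phn
        sev = rng.choice(len(PAIN_STATES), size=idx.size, p=phn_probs)
        loss = loss + has_phn * u * (1.0 - phn_mult[sev]) * phn_durations[sev] / 12.0
        pain_months = np.where(has_phn, phn_durations[sev], epi.duration_months["hz"])

        cat = rng.choice(len(cats), size=idx.size, p=mix)
        antiviral = (rng.random(idx.size) < antiviral_uptake[cat]) * costs.antiviral_course
        analgesic = (
            (rng.random(idx.size) < analgesic_uptake[cat])
            * costs.analgesic_per_month
            * pain_months
        )
        qalys[idx] -= loss * disc[t]
        cost[idx] += (visit_cost[cat] + antiviral + analgesic) * disc[t]

    def agg(x: np.ndarray):
        total = x.mean() * size
        se = x.std(ddof=1) / np.sqrt(n_persons) * size
        return float(total), float(se)

    return {
        "episodes": agg(episodes),
        "phn_cases": agg(phn_cases),
        "qalys_discounted": agg(qalys),
        "hz_cost_discounted": agg(cost),
    }
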