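"""Cohort engine: episode outcomes, conservation, discounting, oracle checks."""

import numpy as np
import pytest

from helpers_microsim import microsimulate
from zoster_cea import (
    CohortSpec,
    ParameterError,
    build_protection_profile,
    episode_cost,
    episode_outcome,
    episode_qaly_loss,
    run_cohort,
    with_path,
)
from zoster_cea.parameters import PAIN_STATES, SEVERITIES


def _phn_zero(params):
    out = params
    for band in ("65-69", "70-74", "75-79", "80-84", "85+"):
        out = with_path(out, f"epidemiology/phn_given_hz/{band}", {"mean": 0.0})
    return out


class TestEpisodeQalyLoss:
    @pytest.mark.parametrize("age,sex", [(65, "female"), (72, "female"), (85, "male")])
    def test_exhaustive_pathway_enumeration(self, basecase, age, sex):
        """Brute-force expectation over every (acute severity, PHN, PHN
        severity) combination must equal the closed-form loss."""
        epi, util = basecase.epidemiology, basecase.utilities
        u = util.baseline_utility(age, sex)
        p_phn = epi.phn_mean(age)
        dur = epi.duration_months
        expected = 0.0
        for s_a in SEVERITIES:
            p_a = epi.hz_severity(age)[s_a]
            acute = u * (1 - util.multiplier(s_a)) * dur["hz"] / 12
            # no PHN branch
            expected += p_a * (1 - p_phn) * acute
            # PHN branches
            for s_p in PAIN_STATES:
                p_p = epi.phn_pain_severity[s_p]
                phn = u * (1 - util.multiplier(s_p)) * dur[s_p] / 12
                expected += p_a * p_phn * p_p * (acute + phn)
        assert episode_qaly_loss(age, sex, basecase) == pytest.approx(expected, rel=1e-12)

    def test_no_decrement_when_multipliers_are_one(self, basecase):
        p = basecase
        for s in PAIN_STATES:
            p = with_path(p, f"utilities/pain_multipliers/{s}", {"mean": 1.0})
        assert episode_qaly_loss(70, "female", p) == 0.0

    def test_phn_branch_off(self, basecase):
        p = _phn_zero(basecase)
        epi, util = p.epidemiology, p.utilities
        u = util.baseline_utility(65, "female")
        acute_only = (
            sum(q * (1 - util.multiplier(s)) for s, q in epi.hz_severity(65).items())
            * u
            / 12
        )
        assert episode_qaly_loss(65, "female", p) == pytest.approx(acute_only, rel=1e-12)


class TestEpisodeCost:
    def test_uncomplicated_case_hand_sum(self, basecase):
        """Pure B02.9 pathway without PHN: visits plus medication, summed by
        hand from the published unit inputs."""
        p = _phn_zero(basecase)
        p = with_path(
            p,
            "utilization/category_mix",
            {"B02.9": 1.0, "B02.2": 0.0, "B02.3": 0.0, "B02.7": 0.0, "B02.8": 0.0},
        )
        hand = 1.17 * 182 + 0.14 * 369 + 0.05 * 5180 + 0.62 * 18.7 + 0.20 * 16.6 * 1
        assert episode_cost(65, "female", p) == pytest.approx(hand, rel=1e-12)

    def test_zero_visits_and_uptakes_zero_cost(self, basecase):
        p = basecase
        for cat in ("B02.9", "B02.2", "B02.3", "B02.7", "B02.8"):
            p = with_path(
                p, f"utilization/visits/{cat}", {"primary": 0.0, "outpatient": 0.0, "inpatient": 0.0}
            )
        for cls in ("uncomplicated", "complicated"):
            p = with_path(
                p, f"utilization/medication_uptake/{cls}", {"antivirals": 0.0, "analgesics": 0.0}
            )
        assert episode_cost(65, "female", p) == 0.0

    def test_complicated_episode_costs_more(self, basecase):
        pure = {"B02.9": 0.0, "B02.2": 0.0, "B02.3": 0.0, "B02.7": 0.0, "B02.8": 0.0}
        p9 = with_path(basecase, "utilization/category_mix", {**pure, "B02.9": 1.0})
        p2 = with_path(basecase, "utilization/category_mix", {**pure, "B02.2": 1.0})
        assert episode_cost(65, "female", p2) > episode_cost(65, "female", p9)

    def test_outcome_components_sum(self, basecase):
        o = episode_outcome(70, "male", basecase)
        assert o.cost == pytest.approx(o.visit_cost + o.medication_cost)
        assert o.qaly_loss == pytest.approx(episode_qaly_loss(70, "male", basecase))


class TestRunCohort:
    def test_occupancy_conservation_exact(self, basecase):
        spec = CohortSpec(65, "female", 272568, "no_vaccination")
        trace = run_cohort(spec, basecase)
        running = spec.size - np.cumsum(trace.deaths)
        assert np.allclose(trace.alive[1:], running[:-1], rtol=0, atol=1e-6)
        assert np.all(trace.alive >= 0)
        assert np.all(trace.episodes <= trace.alive)

    def test_zero_incidence_pure_survival_qalys(self, basecase):
        p = basecase
        for band in ("65-69", "70-74", "75-79", "80-84", "85-89", "90-94", "95-99", "100+"):
            p = with_path(p, f"epidemiology/hz_incidence/{band}", {"female": 0.0, "male": 0.0})
        spec = CohortSpec(65, "male", 1000.0, "no_vaccination")
        trace = run_cohort(spec, p)
        assert trace.total_hz_cost_discounted == 0.0
        # independent survival-weighted accumulation
        expected, surv = 0.0, 1000.0
        for t in range(p.economics.max_age - 65 + 1):
            age = 65 + t
            surv *= 1 - p.demography.death_prob(age, "male")
            expected += surv * p.utilities.baseline_utility(age, "male") * 1.03 ** (-t)
        assert trace.total_qalys_discounted == pytest.approx(expected, rel=1e-12)

    def test_certain_death_empties_cohort(self, basecase):
        p = basecase
        for band in ("65-69", "70-74", "75-79", "80-84", "85-89", "90-94", "95-99", "100+"):
            p = with_path(p, f"demography/death_probability/{band}", {"female": 1.0, "male": 1.0})
        trace = run_cohort(CohortSpec(65, "female", 1.0, "no_vaccination"), p)
        assert np.all(trace.alive[1:] == 0.0)
        assert trace.deaths[0] == 1.0
        assert trace.total_episodes == 0.0

    def test_zero_discount_rate_equalises_totals(self, basecase):
        p = with_path(basecase, "economics/discount_rate", 0.0)
        trace = run_cohort(CohortSpec(65, "female", 1000.0, "no_vaccination"), p)
        assert trace.total_qalys_discounted == pytest.approx(float(trace.qalys.sum()), rel=1e-9)
        assert trace.total_hz_cost_discounted == pytest.approx(float(trace.hz_costs.sum()), rel=1e-9)

    def test_linearity_in_cohort_size(self, basecase):
        protection = build_protection_profile(
            basecase.scenarios["rct"], basecase.program, 41
        )
        t1 = run_cohort(CohortSpec(65, "female", 1000.0, "rzv"), basecase, protection)
        t2 = run_cohort(CohortSpec(65, "female", 2000.0, "rzv"), basecase, protection)
        for name in ("episodes", "qalys", "visit_costs", "vaccination_costs"):
            assert np.allclose(getattr(t2, name), 2 * getattr(t1, name), rtol=1e-12)

    def test_vaccinated_arm_never_has_more_episodes(self, basecase):
        protection = build_protection_profile(
            basecase.scenarios["observational"], basecase.program, 41
        )
        vax = run_cohort(CohortSpec(65, "male", 267652, "rzv"), basecase, protection)
        novax = run_cohort(CohortSpec(65, "male", 267652, "no_vaccination"), basecase)
        assert np.all(vax.episodes <= novax.episodes + 1e-12)

    def test_protection_horizon_too_short_raises(self, basecase):
        protection = build_protection_profile(basecase.scenarios["rct"], basecase.program, 5)
        with pytest.raises(ParameterError, match="horizon"):
            run_cohort(CohortSpec(65, "female", 100.0, "rzv"), basecase, protection)

    def test_rzv_arm_requires_protection(self, basecase):
        with pytest.raises(ParameterError, match="protection"):
            run_cohort(CohortSpec(65, "female", 100.0, "rzv"), basecase, None)

    def test_trace_dataframe_shape(self, basecase):
        trace = run_cohort(CohortSpec(80, "female", 100.0, "no_vaccination"), basecase)
        df = trace.to_dataframe()
        assert len(df) == basecase.economics.max_age - 80 + 1
        assert df["age"].iloc[0] == 80 and df["age"].iloc[-1] == 105
        breakdown = trace.pathway_breakdown(basecase)
        assert breakdown["episodes"].sum() == pytest.approx(trace.total_episodes)


class TestMicrosimulationAgreement:
    def test_expectation_engine_matches_sampling_oracle(self, basecase, rng):
        """Three-cycle toy cohort: engine expectations vs 200k simulated
        persons, within 3 Monte-Carlo standard errors."""
        toy = with_path(basecase, "economics/max_age", 67)
        protection = build_protection_profile(toy.scenarios["rct"], toy.program, 3)
        for arm, mult in (("no_vaccination", None), ("rzv", protection.multipliers)):
            trace = run_cohort(
                CohortSpec(65, "female", 100.0, arm), toy,
                protection if arm == "rzv" else None,
            )
            sim = microsimulate(toy, 65, "female", 100.0, mult, 200_000, rng)
            engine = {
                "episodes": trace.total_episodes,
                "phn_cases": trace.total_phn_cases,
                "qalys_discounted": trace.total_qalys_discounted,
                "hz_cost_discounted": trace.total_hz_cost_discounted,
            }
            for key, (total, se) in sim.items():
                assert abs(engine[key] - total) < 3 * se, (arm, key, engine[key], total, se)
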