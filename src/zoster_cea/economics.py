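"""Incremental cost-effectiveness: ICERs, threshold prices, combined cohorts.

The comparison is always two-dose RZV vaccination versus no vaccination for
one five-year age cohort (both sexes pooled).  Net cost is the vaccination
cost minus the discounted HZ-cost offset; the ICER divides it by the
discounted QALY gain.  Because net cost is linear in the vaccine price per
dose, the price at which the ICER equals a willingness-to-pay threshold has
a closed form, verified here by re-running the model at the solution (with
a bisection fallback guarding optional nonlinear add-ons).

Combined 65+/70+/75+ results use the population-size-weighted mean of the
cohort ICERs — the estimator the underlying evaluation reports — with the
pooled-increment ratio also available, clearly labelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import pandas as pd
from scipy.optimize import brentq

from .cohort import CohortSpec, CohortTrace, START_AGES, run_cohort
from .parameters import ParameterError, ParameterSet, SEXES, with_path
from .protection import build_protection_profile

__all__ = [
    "CEResult",
    "ThresholdPriceResult",
    "run_arm",
    "evaluate_cohort",
    "incremental_result",
    "threshold_price",
    "combined_cohort_icer",
    "pooled_icer",
    "price_sweep",
    "evaluate_all_cohorts",
    "cohort_label",
]

Traces = Union[CohortTrace, Sequence[CohortTrace]]


def cohort_label(start_age: int) -> str:
    return "100+" if start_age >= 100 else f"{start_age}-{start_age + 4}"


@dataclass(frozen=True)
class CEResult:
    """Vaccination-versus-no-vaccination comparison for one cohort.

    Monetary fields are discounted 2021 EUR; case counts are undiscounted
    expected episode counts.  ``icer`` is ``None`` (flagged, never an
    infinity) when the QALY gain is not strictly positive.
    """

    label: str
    scenario_id: Optional[str]
    cohort_size: float
    doses: float
    inc_qalys: float
    vaccination_cost: float
    hz_cost_offset: float  # positive = costs avoided by vaccination
    hz_cases_vax: float
    hz_cases_novax: float
    phn_cases_vax: float
    phn_cases_novax: float
    qalys_vax: float
    qalys_novax: float
    hz_costs_vax: float
    hz_costs_novax: float

    @property
    def net_cost(self) -> float:
        return self.vaccination_cost - self.hz_cost_offset

    @property
    def hz_cases_averted(self) -> float:
        return self.hz_cases_novax - self.hz_cases_vax

    @property
    def phn_cases_averted(self) -> float:
        return self.phn_cases_novax - self.phn_cases_vax

    @property
    def icer_defined(self) -> bool:
        return self.inc_qalys > 0.0

    @property
    def icer(self) -> Optional[float]:
        if not self.icer_defined:
            return None
        return self.net_cost / self.inc_qalys

    def net_monetary_benefit(self, wtp: float) -> float:
        return wtp * self.inc_qalys - self.net_cost

    def summary(self) -> pd.Series:
        """Outcome table shaped like the published per-cohort results."""
        return pd.Series(
            {
                "cohort": self.label,
                "scenario": self.scenario_id,
                "hz_cases_rzv": self.hz_cases_vax,
                "hz_cases_no_vaccination": self.hz_cases_novax,
                "hz_cases_averted": self.hz_cases_averted,
                "phn_cases_rzv": self.phn_cases_vax,
                "phn_cases_no_vaccination": self.phn_cases_novax,
                "phn_cases_averted": self.phn_cases_averted,
                "qalys_rzv": self.qalys_vax,
                "qalys_no_vaccination": self.qalys_novax,
                "incremental_qalys": self.inc_qalys,
                "vaccination_costs": self.vaccination_cost,
                "hz_costs_rzv": self.hz_costs_vax,
                "hz_costs_no_vaccination": self.hz_costs_novax,
                "hz_cost_offset": self.hz_cost_offset,
                "net_cost": self.net_cost,
                "icer": self.icer if self.icer_defined else float("nan"),
            }
        )


def run_arm(
    params: ParameterSet,
    start_age: int,
    arm: str,
    scenario_id: Optional[str] = None,
    sexes: Sequence[str] = SEXES,
) -> Tuple[CohortTrace, ...]:
    """Run one arm for every requested sex of one age cohort."""
    protection = None
    if arm == "rzv":
        if scenario_id is None:
            raise ParameterError("the rzv arm requires an efficacy scenario id")
        try:
            scenario = params.scenarios[scenario_id]
        except KeyError:
            raise ParameterError(
                f"unknown efficacy scenario {scenario_id!r}; available: "
                f"{sorted(params.scenarios)}"
            ) from None
        horizon = params.economics.max_age - start_age + 1
        protection = build_protection_profile(scenario, params.program, horizon)
    band = cohort_label(start_age)
    traces = []
    for sex in sexes:
        spec = CohortSpec(
            start_age=start_age,
            sex=sex,
            size=params.demography.size(band, sex),
            arm=arm,
        )
        traces.append(run_cohort(spec, params, protection))
    return tuple(traces)


def _as_traces(traces: Traces) -> Tuple[CohortTrace, ...]:
    if isinstance(traces, CohortTrace):
        return (traces,)
    return tuple(traces)


def incremental_result(
    vax: Traces,
    novax: Traces,
    scenario_id: Optional[str] = None,
    label: Optional[str] = None,
) -> CEResult:
    """Difference two arms of the same cohort into a :class:`CEResult`.

    Accepts single traces or matching sequences (e.g. one per sex); traces
    must agree on start age, sex and size, differing only in arm.
    """
    vax_t, novax_t = _as_traces(vax), _as_traces(novax)
    if len(vax_t) != len(novax_t) or not vax_t:
        raise ParameterError("arm trace collections must be non-empty and equal-length")
    for a, b in zip(vax_t, novax_t):
        same = (
            a.spec.start_age == b.spec.start_age
            and a.spec.sex == b.spec.sex
            and a.spec.size == b.spec.size
        )
        if not same:
            raise ParameterError(
                f"mismatched cohorts: {a.spec} vs {b.spec} (must differ only in arm)"
            )
        if a.spec.arm != "rzv" or b.spec.arm != "no_vaccination":
            raise ParameterError(
                "expected (rzv, no_vaccination) arm pair, got "
                f"({a.spec.arm!r}, {b.spec.arm!r})"
            )

    qalys_vax = sum(t.total_qalys_discounted for t in vax_t)
    qalys_novax = sum(t.total_qalys_discounted for t in novax_t)
    hz_costs_vax = sum(t.total_hz_cost_discounted for t in vax_t)
    hz_costs_novax = sum(t.total_hz_cost_discounted for t in novax_t)
    vaccination = sum(t.total_vaccination_cost_discounted for t in vax_t)
    size = sum(t.spec.size for t in vax_t)
    return CEResult(
        label=label or cohort_label(vax_t[0].spec.start_age),
        scenario_id=scenario_id,
        cohort_size=size,
        doses=float("nan"),  # traces do not carry the programme; set by evaluate_cohort
        inc_qalys=qalys_vax - qalys_novax,
        vaccination_cost=vaccination,
        hz_cost_offset=hz_costs_novax - hz_costs_vax,
        hz_cases_vax=sum(t.total_episodes for t in vax_t),
        hz_cases_novax=sum(t.total_episodes for t in novax_t),
        phn_cases_vax=sum(t.total_phn_cases for t in vax_t),
        phn_cases_novax=sum(t.total_phn_cases for t in novax_t),
        qalys_vax=qalys_vax,
        qalys_novax=qalys_novax,
        hz_costs_vax=hz_costs_vax,
        hz_costs_novax=hz_costs_novax,
    )


def evaluate_cohort(
    params: ParameterSet, start_age: int, scenario_id: str
) -> CEResult:
    """Full vaccination-versus-none evaluation of one cohort, both sexes."""
    vax = run_arm(params, start_age, "rzv", scenario_id)
    novax = run_arm(params, start_age, "no_vaccination")
    result = incremental_result(vax, novax, scenario_id=scenario_id)
    prog = params.program
    doses = result.cohort_size * prog.coverage * prog.doses_per_first_dose_recipient
    return _with_doses(result, doses)


def _with_doses(result: CEResult, doses: float) -> CEResult:
    from dataclasses import replace

    return replace(result, doses=doses)


@dataclass(frozen=True)
class ThresholdPriceResult:
    """Vaccine price per dose at which the ICER meets the WTP.

    ``status`` is ``"ok"`` when a non-negative solution exists,
    ``"cost_saving"`` when the intervention is cheaper than no vaccination
    even at the requested price floor of zero being exceeded (net cost at
    the solved price would need a negative price), and
    ``"no_qaly_gain"`` when the QALY gain is not positive so no threshold
    price exists.
    """

    wtp: float
    price_per_dose: Optional[float]
    status: str
    doses: float
    slope: float  # d(net cost)/d(price) = doses delivered
    intercept: float  # net cost at price zero
    inc_qalys: float
    achieved_icer: Optional[float] = None


def threshold_price(
    params: ParameterSet,
    start_age: int,
    scenario_id: str,
    wtp: Optional[float] = None,
    rel_tol: float = 1e-6,
) -> ThresholdPriceResult:
    """Solve for the vaccine price per dose at which ICER equals ``wtp``.

    Uses the linearity of net cost in price — ``net(price) = slope * price
    + intercept`` with slope equal to the doses delivered — then verifies by
    re-running the model at the solution and falls back to bisection if the
    re-run misses the target beyond ``rel_tol`` (possible only for
    nonlinear add-ons).
    """
    wtp = params.economics.wtp_per_qaly if wtp is None else wtp
    if wtp <= 0:
        raise ParameterError(f"wtp must be > 0, got {wtp}")

    price_path = "costs/vaccine_price_per_dose"

    def net_at(price: float) -> Tuple[float, float]:
        res = evaluate_cohort(with_path(params, price_path, price), start_age, scenario_id)
        return res.net_cost, res.inc_qalys

    p0 = params.costs.vaccine_price_per_dose
    net0, dq0 = net_at(p0)
    net1, dq1 = net_at(p0 + 100.0)
    slope = (net1 - net0) / 100.0
    intercept = net0 - slope * p0

    if dq0 <= 0.0:
        return ThresholdPriceResult(
            wtp=wtp, price_per_dose=None, status="no_qaly_gain", doses=slope,
            slope=slope, intercept=intercept, inc_qalys=dq0,
        )
    if slope <= 0.0:
        raise ParameterError("net cost is not increasing in price; cannot invert")

    price = (wtp * dq0 - intercept) / slope
    if price < 0.0:
        return ThresholdPriceResult(
            wtp=wtp, price_per_dose=None, status="cost_saving", doses=slope,
            slope=slope, intercept=intercept, inc_qalys=dq0,
        )

    net_star, dq_star = net_at(price)
    icer_star = net_star / dq_star
    if abs(icer_star - wtp) / wtp > rel_tol:
        # nonlinearity guard: bisect on ICER(price) - wtp
        def f(p: float) -> float:
            net, dq = net_at(p)
            return net / dq - wtp

        hi = max(p0, price) * 10.0 + 1.0
        price = brentq(f, 0.0, hi, xtol=1e-9, rtol=1e-12)
        net_star, dq_star = net_at(price)
        icer_star = net_star / dq_star

    return ThresholdPriceResult(
        wtp=wtp,
        price_per_dose=float(price),
        status="ok",
        doses=slope,
        slope=slope,
        intercept=intercept,
        inc_qalys=dq0,
        achieved_icer=float(icer_star),
    )


def combined_cohort_icer(
    results: Sequence[CEResult], weights: Optional[Sequence[float]] = None
) -> float:
    """Population-size-weighted mean of cohort ICERs.

    This is the combined-cohort estimator the evaluation reports (the mean
    of the per-cohort ICERs weighted by cohort size), not the ratio of
    pooled incremental sums — see :func:`pooled_icer` for that.  Undefined
    ICERs are an error naming the offending cohorts.
    """
    if not results:
        raise ParameterError("need at least one cohort result")
    undefined = [r.label for r in results if not r.icer_defined]
    if undefined:
        raise ParameterError(f"undefined ICER for cohorts: {undefined}")
    if weights is None:
        weights = [r.cohort_size for r in results]
    if len(weights) != len(results):
        raise ParameterError("weights must match results one-to-one")
    if any(w <= 0 for w in weights):
        raise ParameterError("weights must be > 0")
    total = float(sum(weights))
    return float(sum(w * r.icer for w, r in zip(weights, results)) / total)


def pooled_icer(results: Sequence[CEResult]) -> float:
    """Ratio of pooled incremental costs to pooled incremental QALYs."""
    if not results:
        raise ParameterError("need at least one cohort result")
    dq = sum(r.inc_qalys for r in results)
    if dq <= 0:
        raise ParameterError("pooled QALY gain is not positive")
    return float(sum(r.net_cost for r in results) / dq)


def evaluate_all_cohorts(
    params: ParameterSet, scenario_id: str, start_ages: Sequence[int] = START_AGES
) -> Tuple[CEResult, ...]:
    return tuple(evaluate_cohort(params, a, scenario_id) for a in start_ages)


def price_sweep(
    params: ParameterSet,
    start_ages: Sequence[int],
    scenario_id: str,
    prices: Sequence[float],
) -> pd.DataFrame:
    """ICER as a function of vaccine price per dose, per cohort.

    Tidy output (columns ``cohort``, ``scenario``, ``price_per_dose``,
    ``net_cost``, ``incremental_qalys``, ``icer``) matching the shape of
    the published cost-per-QALY-versus-price figures.
    """
    rows = []
    for price in prices:
        p = with_path(params, "costs/vaccine_price_per_dose", float(price))
        for age in start_ages:
            res = evaluate_cohort(p, age, scenario_id)
            rows.append(
                {
                    "cohort": res.label,
                    "scenario": scenario_id,
                    "price_per_dose": float(price),
                    "net_cost": res.net_cost,
                    "incremental_qalys": res.inc_qalys,
                    "icer": res.icer if res.icer_defined else float("nan"),
                }
            )
    return pd.DataFrame(rows)
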