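"""One-way and probabilistic sensitivity analyses.

One-way scenarios replace named parameters (by '/'-separated path), scale
all healthcare unit costs, or move the PHN proportions to their interval
bounds, then re-run the deterministic model.  The probabilistic analysis
re-draws every uncertain parameter from its declared distribution
(:func:`zoster_cea.parameters.draw_parameters`) for each of ``n_draws``
full model evaluations and summarises the incremental outcomes by their
mean and empirical 2.5th/97.5th percentiles.

Random-stream discipline: one master seed spawns an independent child
stream per draw, so adding a parameter to the model does not perturb the
values other draws see, and the same seed reproduces draws bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .economics import CEResult, evaluate_cohort
from .parameters import (
    PHN_BANDS,
    ParameterError,
    ParameterSet,
    draw_parameters,
    with_path,
)

__all__ = [
    "OneWayScenario",
    "apply_one_way",
    "run_one_way",
    "table3_scenarios",
    "PSAResult",
    "run_psa",
    "CEACPoint",
    "ceac",
    "tornado",
]

#: healthcare unit-cost fields scaled by ``OneWayScenario.cost_scale``
#: (the vaccine price per dose is the decision variable and is excluded)
_SCALED_COSTS = (
    "administration_per_dose",
    "primary_care_visit",
    "inpatient_episode",
    "antiviral_course",
    "analgesic_per_month",
)


@dataclass(frozen=True)
class OneWayScenario:
    """A named, exactly reproducible deterministic what-if.

    ``overrides`` maps parameter paths to replacement values;
    ``cost_scale`` multiplies every healthcare unit cost (vaccine price
    excluded); ``phn_ci`` moves all PHN proportions to ``"low"`` or
    ``"high"`` mean +/- 1.96 SE bounds (a normal approximation to the
    unpublished meta-analytic interval limits).  ``group`` labels low/high
    pairs for tornado plotting.
    """

    name: str
    overrides: Mapping[str, Any] = field(default_factory=dict)
    cost_scale: float = 1.0
    phn_ci: Optional[str] = None
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.phn_ci not in (None, "low", "high"):
            raise ParameterError(f"phn_ci must be None, 'low' or 'high', got {self.phn_ci!r}")
        if self.cost_scale <= 0:
            raise ParameterError("cost_scale must be > 0")


def apply_one_way(params: ParameterSet, scenario: OneWayScenario) -> ParameterSet:
    """Apply a one-way scenario to a base parameter set and revalidate."""
    out = params
    for path in sorted(scenario.overrides):
        out = with_path(out, path, scenario.overrides[path])
    if scenario.cost_scale != 1.0:
        for name in _SCALED_COSTS:
            out = with_path(out, f"costs/{name}", getattr(out.costs, name) * scenario.cost_scale)
        scaled = {k: v * scenario.cost_scale for k, v in out.costs.outpatient_visit.items()}
        out = with_path(out, "costs/outpatient_visit", scaled)
    if scenario.phn_ci is not None:
        sign = -1.96 if scenario.phn_ci == "low" else 1.96
        for band in PHN_BANDS:
            entry = dict(out.epidemiology.phn_given_hz[band])
            se = entry.get("se")
            if se is None:
                raise ParameterError(
                    f"phn_ci bound requested but phn_given_hz[{band}] has no SE"
                )
            entry["mean"] = float(np.clip(entry["mean"] + sign * se, 1e-9, 1 - 1e-9))
            out = with_path(out, f"epidemiology/phn_given_hz/{band}", entry)
    return out.validate()


def table3_scenarios() -> tuple:
    """The published one-way sensitivity set constructible from the fixture.

    The stroke add-on and the four alternative HRQoL-multiplier sets are
    also runnable through :class:`OneWayScenario` overrides but need
    user-supplied values (they are not published), so they ship as empty
    slots rather than here.
    """
    return (
        OneWayScenario("0% discount", {"economics/discount_rate": 0.0}, group="discounting"),
        OneWayScenario("5% discount", {"economics/discount_rate": 0.05}, group="discounting"),
        OneWayScenario("dose-1 uptake 50%", {"program/coverage": 0.50}, group="dose-1 uptake"),
        OneWayScenario("dose-1 uptake 70%", {"program/coverage": 0.70}, group="dose-1 uptake"),
        OneWayScenario(
            "dose-2 compliance 50%",
            {"program/compliance_second_dose": 0.50},
            group="dose-2 compliance",
        ),
        OneWayScenario(
            "dose-2 compliance 100%",
            {"program/compliance_second_dose": 1.0},
            group="dose-2 compliance",
        ),
        OneWayScenario(
            "no protection after 10 years",
            {
                "scenarios/rct/zero_after_10_years": True,
                "scenarios/observational/zero_after_10_years": True,
            },
            group="waning",
        ),
        OneWayScenario("PHN proportion lower bound", phn_ci="low", group="PHN proportion"),
        OneWayScenario("PHN proportion upper bound", phn_ci="high", group="PHN proportion"),
        OneWayScenario("unit costs -40%", cost_scale=0.6, group="unit costs"),
        OneWayScenario("unit costs +40%", cost_scale=1.4, group="unit costs"),
    )


def run_one_way(
    params: ParameterSet,
    scenarios: Sequence[OneWayScenario],
    start_ages: Sequence[int],
    scenario_ids: Sequence[str] = ("rct", "observational"),
    include_base: bool = True,
) -> pd.DataFrame:
    """One deterministic run per (what-if x cohort x efficacy scenario).

    Returns a tidy table mirroring the published one-way layout: columns
    ``analysis``, ``group``, ``cohort``, ``scenario``, ``icer``,
    ``net_cost``, ``incremental_qalys``.
    """
    rows = []

    def add(name: str, group: Optional[str], p: ParameterSet) -> None:
        for age in start_ages:
            for sid in scenario_ids:
                res = evaluate_cohort(p, age, sid)
                rows.append(
                    {
                        "analysis": name,
                        "group": group,
                        "cohort": res.label,
                        "scenario": sid,
                        "icer": res.icer if res.icer_defined else float("nan"),
                        "net_cost": res.net_cost,
                        "incremental_qalys": res.inc_qalys,
                    }
                )

    if include_base:
        add("basecase", None, params)
    for sc in scenarios:
        add(sc.name, sc.group, apply_one_way(params, sc))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PSAResult:
    """Per-draw incremental outcomes of the probabilistic analysis.

    Arrays are aligned by draw.  ``icers`` is NaN for draws without a
    positive QALY gain (none occur under the shipped fixture).  Summaries
    report the empirical 2.5th/97.5th percentiles — a 95% credible
    interval — alongside the mean.
    """

    label: str
    scenario_id: str
    seed: int
    n_draws: int
    inc_qalys: np.ndarray
    cost_offsets: np.ndarray
    net_costs: np.ndarray
    icers: np.ndarray
    vaccination_cost: float

    def _summary_row(self, values: np.ndarray) -> dict:
        finite = values[np.isfinite(values)]
        lo, hi = np.percentile(finite, [2.5, 97.5])
        return {
            "mean": float(finite.mean()),
            "cri_2.5": float(lo),
            "cri_97.5": float(hi),
        }

    def summary(self) -> pd.DataFrame:
        """Mean and 95% credible interval per incremental outcome."""
        data = {
            "incremental_qalys": self._summary_row(self.inc_qalys),
            "hz_cost_offset": self._summary_row(self.cost_offsets),
            "net_cost": self._summary_row(self.net_costs),
            "icer_per_draw": self._summary_row(self.icers),
        }
        out = pd.DataFrame(data).T
        out.index.name = "outcome"
        return out

    @property
    def icer_ratio_of_means(self) -> float:
        """Mean net cost over mean QALY gain (the CrIs attach to increments,
        not to this ratio)."""
        return float(self.net_costs.mean() / self.inc_qalys.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(self.n_draws),
                "incremental_qalys": self.inc_qalys,
                "hz_cost_offset": self.cost_offsets,
                "net_cost": self.net_costs,
                "icer": self.icers,
            }
        )


def run_psa(
    params: ParameterSet,
    start_age: int,
    scenario_id: str,
    n_draws: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Monte Carlo parameter uncertainty: ``n_draws`` full model runs."""
    if n_draws < 2:
        raise ParameterError(f"n_draws must be >= 2, got {n_draws}")
    children = np.random.SeedSequence(seed).spawn(n_draws)
    inc_qalys = np.empty(n_draws)
    offsets = np.empty(n_draws)
    nets = np.empty(n_draws)
    icers = np.empty(n_draws)
    label = None
    vaccination = np.nan
    for i, child in enumerate(children):
        drawn = draw_parameters(params, np.random.default_rng(child))
        res = evaluate_cohort(drawn, start_age, scenario_id)
        inc_qalys[i] = res.inc_qalys
        offsets[i] = res.hz_cost_offset
        nets[i] = res.net_cost
        icers[i] = res.icer if res.icer_defined else np.nan
        label = res.label
        vaccination = res.vaccination_cost
    return PSAResult(
        label=label,
        scenario_id=scenario_id,
        seed=seed,
        n_draws=n_draws,
        inc_qalys=inc_qalys,
        cost_offsets=offsets,
        net_costs=nets,
        icers=icers,
        vaccination_cost=vaccination,
    )


@dataclass(frozen=True)
class CEACPoint:
    """One point of the cost-effectiveness acceptability curve."""

    wtp: float
    probability: float


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> tuple:
    """P(net monetary benefit > 0) across draws, per WTP grid point."""
    if len(wtp_grid) == 0:
        raise ParameterError("wtp_grid must be non-empty")
    points = []
    for wtp in wtp_grid:
        nmb = wtp * psa.inc_qalys - psa.net_costs
        points.append(CEACPoint(wtp=float(wtp), probability=float((nmb > 0).mean())))
    return tuple(points)


def ceac_frame(points: Sequence[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame([{"wtp": p.wtp, "probability": p.probability} for p in points])


def tornado(base: CEResult, one_way: pd.DataFrame) -> pd.DataFrame:
    """Order one-way results by their pull on the ICER (largest first).

    ``one_way`` is the output of :func:`run_one_way`, filtered to one
    cohort and one efficacy scenario; the basecase row, if present, is
    dropped.  Low/high pairs stay adjacent via the ``group`` column.
    """
    if not base.icer_defined:
        raise ParameterError("base result has no defined ICER")
    if len(one_way) == 0:
        raise ParameterError("need at least one one-way scenario")
    df = one_way[one_way["analysis"] != "basecase"].copy()
    df["base_icer"] = base.icer
    df["delta_icer"] = df["icer"] - base.icer
    df["abs_delta"] = df["delta_icer"].abs()
    df["group"] = df["group"].fillna(df["analysis"])
    order = (
        df.groupby("group", sort=False)["abs_delta"].max().sort_values(ascending=False)
    )
    df["group_rank"] = df["group"].map({g: i for i, g in enumerate(order.index)})
    df = df.sort_values(
        ["group_rank", "abs_delta"], ascending=[True, False]
    ).drop(columns="group_rank")
    return df.reset_index(drop=True)
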