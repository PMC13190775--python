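"""One-way scenarios, probabilistic sensitivity analysis, CEAC, tornado."""

import numpy as np
import pytest

from zoster_cea import (
    OneWayScenario,
    ParameterError,
    apply_one_way,
    ceac,
    evaluate_cohort,
    run_one_way,
    run_psa,
    strip_uncertainty,
    table3_scenarios,
    tornado,
)
from zoster_cea.uncertainty import PSAResult
from zoster_cea.parameters import PHN_BANDS
import pandas as pd


def _synthetic_psa(inc_qalys, net_costs):
    inc = np.asarray(inc_qalys, dtype=float)
    net = np.asarray(net_costs, dtype=float)
    return PSAResult(
        label="65-69",
        scenario_id="rct",
        seed=0,
        n_draws=len(inc),
        inc_qalys=inc,
        cost_offsets=np.zeros_like(inc),
        net_costs=net,
        icers=net / inc,
        vaccination_cost=0.0,
    )


class TestOneWay:
    def test_empty_override_reproduces_base(self, basecase):
        base = evaluate_cohort(basecase, 65, "rct").icer
        same = evaluate_cohort(
            apply_one_way(basecase, OneWayScenario("noop")), 65, "rct"
        ).icer
        assert same == base

    def test_unknown_path_named_in_error(self, basecase):
        sc = OneWayScenario("bad", {"economics/discount_rte": 0.0})
        with pytest.raises(ParameterError, match="discount_rte"):
            apply_one_way(basecase, sc)

    def test_cost_scale_scales_offset_exactly(self, basecase):
        """Every HZ cost component is a unit cost times utilisation, so a
        40% unit-cost cut scales the cost offset by exactly 0.6."""
        base = evaluate_cohort(basecase, 65, "rct")
        low = evaluate_cohort(
            apply_one_way(basecase, OneWayScenario("lc", cost_scale=0.6)), 65, "rct"
        )
        assert low.hz_cost_offset == pytest.approx(0.6 * base.hz_cost_offset, rel=1e-9)
        assert low.icer > base.icer  # smaller offset, higher net cost

    def test_phn_ci_bounds_bracket_base(self, basecase):
        lo = apply_one_way(basecase, OneWayScenario("lo", phn_ci="low"))
        hi = apply_one_way(basecase, OneWayScenario("hi", phn_ci="high"))
        for band in PHN_BANDS:
            m = basecase.epidemiology.phn_given_hz[band]["mean"]
            assert lo.epidemiology.phn_given_hz[band]["mean"] < m
            assert hi.epidemiology.phn_given_hz[band]["mean"] > m
        # more PHN -> larger QALY gain -> lower ICER
        assert evaluate_cohort(hi, 65, "rct").icer < evaluate_cohort(lo, 65, "rct").icer

    def test_every_shipped_scenario_is_constructible(self, basecase):
        for sc in table3_scenarios():
            apply_one_way(basecase, sc)  # validates

    def test_run_one_way_layout(self, basecase):
        scenarios = table3_scenarios()[:2]
        table = run_one_way(basecase, scenarios, [65], ("rct",))
        assert list(table["analysis"]) == ["basecase", scenarios[0].name, scenarios[1].name]
        assert set(table.columns) >= {"analysis", "cohort", "scenario", "icer", "net_cost"}


class TestPSA:
    def test_all_fixed_zero_width_intervals(self, basecase):
        fixed = strip_uncertainty(basecase)
        psa = run_psa(fixed, 65, "rct", n_draws=20, seed=3)
        s = psa.summary()
        assert (s["cri_97.5"] - s["cri_2.5"]).abs().max() == pytest.approx(0.0, abs=1e-9)
        det = evaluate_cohort(basecase, 65, "rct")
        assert psa.inc_qalys[0] == pytest.approx(det.inc_qalys, rel=1e-12)

    def test_same_seed_bit_identical(self, basecase):
        a = run_psa(basecase, 65, "rct", n_draws=15, seed=11)
        b = run_psa(basecase, 65, "rct", n_draws=15, seed=11)
        assert np.array_equal(a.inc_qalys, b.inc_qalys)
        assert np.array_equal(a.net_costs, b.net_costs)
        c = run_psa(basecase, 65, "rct", n_draws=15, seed=12)
        assert not np.array_equal(a.inc_qalys, c.inc_qalys)

    def test_mean_converges_to_deterministic_for_linear_outputs(self, basecase):
        """QALY gain is multilinear in the independently drawn parameters,
        so the PSA mean is centred on the deterministic value (reduced
        horizon keeps the run fast)."""
        from zoster_cea import with_path

        reduced = with_path(basecase, "economics/max_age", 75)
        det = evaluate_cohort(reduced, 65, "rct").inc_qalys
        psa = run_psa(reduced, 65, "rct", n_draws=400, seed=5)
        se = psa.inc_qalys.std(ddof=1) / np.sqrt(psa.n_draws)
        assert abs(psa.inc_qalys.mean() - det) < 3.5 * se

    def test_too_few_draws_rejected(self, basecase):
        with pytest.raises(ParameterError):
            run_psa(basecase, 65, "rct", n_draws=1, seed=0)

    def test_draw_frame_shape(self, basecase):
        psa = run_psa(basecase, 65, "rct", n_draws=5, seed=0)
        df = psa.to_frame()
        assert len(df) == 5
        assert {"incremental_qalys", "net_cost", "icer"} <= set(df.columns)


class TestCEAC:
    def test_endpoints(self, basecase):
        psa = run_psa(basecase, 65, "rct", n_draws=30, seed=2)
        points = ceac(psa, [0.0, 1e9])
        assert points[0].probability == 0.0  # all net costs positive
        assert points[-1].probability == 1.0  # all QALY gains positive

    def test_monotone_when_all_gains_positive(self, basecase):
        psa = run_psa(basecase, 65, "rct", n_draws=60, seed=4)
        assert (psa.inc_qalys > 0).all()
        grid = np.linspace(0, 400_000, 21)
        probs = [pt.probability for pt in ceac(psa, grid)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_median_icer_gives_half(self):
        # symmetric synthetic draw set: ICERs 60k..140k around 100k median
        icers = np.array([60, 70, 80, 90, 95, 105, 110, 120, 130, 140]) * 1e3
        psa = _synthetic_psa(np.ones_like(icers), icers)
        (pt,) = ceac(psa, [100_000.0])
        assert pt.probability == pytest.approx(0.5)

    def test_empty_grid_rejected(self, basecase):
        psa = _synthetic_psa([1.0, 1.0], [1.0, 2.0])
        with pytest.raises(ParameterError):
            ceac(psa, [])


class TestTornado:
    def _one_way_frame(self, rows):
        return pd.DataFrame(
            [
                {"analysis": name, "group": group, "cohort": "65-69",
                 "scenario": "rct", "icer": icer, "net_cost": 0.0,
                 "incremental_qalys": 1.0}
                for name, group, icer in rows
            ]
        )

    def test_single_scenario_single_bar(self, basecase):
        base = evaluate_cohort(basecase, 65, "rct")
        t = tornado(base, self._one_way_frame([("x", None, base.icer + 5000)]))
        assert len(t) == 1
        assert t.loc[0, "delta_icer"] == pytest.approx(5000)

    def test_zero_delta_sorted_last_and_groups_ranked(self, basecase):
        base = evaluate_cohort(basecase, 65, "rct")
        frame = self._one_way_frame(
            [
                ("same", None, base.icer),
                ("small-low", "small", base.icer - 1000),
                ("small-high", "small", base.icer + 2000),
                ("big", None, base.icer + 50_000),
            ]
        )
        t = tornado(base, frame)
        assert t.loc[0, "analysis"] == "big"
        assert t.iloc[-1]["analysis"] == "same"
        # low/high pair stays adjacent
        small = t[t["group"] == "small"].index
        assert list(small) == [1, 2]

    def test_published_oneway_set_ranks_waning_above_unit_costs(self, basecase):
        """The duration-of-protection assumption pulls the ICER further
        from base than +/-40% unit costs."""
        base = evaluate_cohort(basecase, 65, "rct")
        table = run_one_way(basecase, table3_scenarios(), [65], ("rct",), include_base=False)
        t = tornado(base, table)
        groups = list(dict.fromkeys(t["group"]))
        assert groups.index("waning") < groups.index("unit costs")
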