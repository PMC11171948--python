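"""One-way DSA, probabilistic sensitivity analysis, CEAC and scenarios."""

import math

import numpy as np
import pandas as pd
import pytest

from ppdcea.model import PRENATAL, ROUTINE, SCREENING
from ppdcea.params import Parameter, ParameterSet
from ppdcea.uncertainty import (
    PSAOutput, ScenarioSpec, ceac, evaluate_strategies, one_way_dsa,
    run_psa, run_scenarios, tornado_frame,
)


def fixed_pset(pset):
    """Every parameter degraded to a point mass at its base value."""
    params = {
        n: Parameter(n, p.base, p.base, p.base, "fixed", p.description, p.calibrated)
        for n, p in pset.params.items()
    }
    return ParameterSet(params, None, pset.constants)


class TestOneWayDsa:
    def test_unused_parameter_has_zero_width(self, pset):
        params = dict(pset.params)
        params["c_unused"] = Parameter("c_unused", 10.0, 8.0, 12.0, "gamma")
        augmented = ParameterSet(params, None, pset.constants)
        entries = one_way_dsa(augmented, parameters=["c_unused"])
        assert entries[0].width == 0.0

    def test_zero_delta_gives_all_zero_widths(self, pset):
        entries = one_way_dsa(pset, delta=0.0)
        assert all(e.width == pytest.approx(0.0, abs=1e-9) for e in entries)

    def test_prevalence_bar_matches_two_direct_evaluations(self, pset):
        from ppdcea.params import perturb

        def icer_at(factor):
            res = evaluate_strategies(perturb(pset, "p_ppd", factor))
            dc = res[PRENATAL][0] - res[ROUTINE][0]
            de = res[PRENATAL][1] - res[ROUTINE][1]
            return dc / de

        entries = {e.parameter: e for e in one_way_dsa(pset)}
        assert entries["p_ppd"].icer_low == pytest.approx(icer_at(0.8))
        assert entries["p_ppd"].icer_high == pytest.approx(icer_at(1.2))
        assert entries["p_ppd"].width == pytest.approx(abs(icer_at(1.2) - icer_at(0.8)))

    def test_entries_sorted_by_descending_width(self, pset):
        widths = [e.width for e in one_way_dsa(pset)]
        assert widths == sorted(widths, reverse=True)
        frame = tornado_frame(one_way_dsa(pset))
        assert list(frame.columns) == ["parameter", "icer_low", "icer_high", "width"]


class TestRunPsa:
    def test_degenerate_psa_equals_rollback(self, pset):
        degenerate = fixed_pset(pset)
        psa = run_psa(degenerate, iterations=1, seed=0)
        base = evaluate_strategies(pset)
        for s, (c, e) in base.items():
            assert psa.costs[s][0] == pytest.approx(c, abs=1e-9)
            assert psa.effects[s][0] == pytest.approx(e, abs=1e-9)

    def test_same_seed_bitwise_identical(self, pset):
        a = run_psa(pset, 300, seed=5)
        b = run_psa(pset, 300, seed=5)
        for s in a.costs:
            assert (a.costs[s] == b.costs[s]).all()
            assert (a.effects[s] == b.effects[s]).all()

    def test_mean_psa_outcome_matches_base_case(self, pset):
        # every path value is multilinear in independent parameters, so the
        # expectation over parameter draws equals the base-case rollback
        iters = 10_000
        psa = run_psa(pset, iters, seed=11)
        base = evaluate_strategies(pset)
        for s, (c, e) in base.items():
            se_c = psa.costs[s].std() / math.sqrt(iters)
            se_e = psa.effects[s].std() / math.sqrt(iters)
            assert abs(psa.costs[s].mean() - c) < 4 * se_c, s
            assert abs(psa.effects[s].mean() - e) < 4 * se_e, s

    def test_microsim_mode_agrees_with_expected_value_mode(self, pset):
        n = 4_000
        ev = run_psa(fixed_pset(pset), 1, seed=3)
        ms = run_psa(fixed_pset(pset), 1, seed=3, mode="microsim", microsim_n=n)
        for s in ev.costs:
            sd = 250.0  # loose: per-individual cost sd is a few hundred USD
            assert abs(ms.costs[s][0] - ev.costs[s][0]) < 4 * sd / math.sqrt(n)

    def test_rejects_bad_inputs(self, pset):
        with pytest.raises(ValueError):
            run_psa(pset, 0, seed=1)
        with pytest.raises(ValueError):
            run_psa(pset, 10, seed=1, mode="bootstrap")


class TestCeac:
    def test_single_strategy_is_always_accepted(self):
        psa = PSAOutput(4, 0, {"only": np.arange(4.0)}, {"only": np.ones(4)})
        curves = ceac(psa, [0, 1000])
        assert (curves["only"] == 1.0).all()

    def test_identical_strategies_split_ties_equally(self):
        c = np.full(10, 5.0)
        e = np.full(10, 0.5)
        psa = PSAOutput(10, 0, {"a": c, "b": c.copy()}, {"a": e, "b": e.copy()})
        curves = ceac(psa, [0, 11300])
        assert (curves["a"] == 0.5).all()
        assert (curves["b"] == 0.5).all()

    def test_probabilities_sum_to_one(self, pset):
        psa = run_psa(pset, 2_000, seed=19)
        curves = ceac(psa, np.arange(0, 30001, 1000))
        strategies = [c for c in curves.columns if c != "wtp"]
        assert np.allclose(curves[strategies].sum(axis=1), 1.0, atol=1e-9)

    def test_acceptance_equals_brute_force_argmax_recount(self, pset):
        psa = run_psa(pset, 500, seed=23)
        strategies = list(psa.costs)
        for w in (1000.0, 11300.0):
            curves = ceac(psa, [w])
            wins = {s: 0.0 for s in strategies}
            for i in range(psa.iterations):
                nmbs = {s: w * psa.effects[s][i] - psa.costs[s][i] for s in strategies}
                best = max(nmbs.values())
                winners = [s for s, v in nmbs.items() if v == best]
                for s in winners:
                    wins[s] += 1.0 / len(winners)
            for s in strategies:
                assert curves[s][0] == pytest.approx(wins[s] / psa.iterations, abs=1e-12)

    def test_prenatal_curve_crosses_half_below_wtp_threshold(self, pset):
        psa = run_psa(pset, 2_000, seed=29)
        grid = np.arange(0, 11301, 100)
        curves = ceac(psa, grid)
        above = curves[curves[PRENATAL] > 0.5]
        assert not above.empty
        assert above["wtp"].iloc[0] < pset.constants["wtp"]

    def test_empty_grid_rejected(self, pset):
        psa = run_psa(pset, 10, seed=1)
        with pytest.raises(ValueError):
            ceac(psa, [])


class TestScenarios:
    def test_identity_scenario_reproduces_base_case(self, pset):
        tables = run_scenarios(pset, [ScenarioSpec("base", cost_multiplier=1.0)])
        base = evaluate_strategies(pset)
        table = tables["base"]
        for s, (c, e) in base.items():
            row = table[table.strategy == s].iloc[0]
            assert row.cost == pytest.approx(c, abs=1e-9)
            assert row.effect == pytest.approx(e, abs=1e-9)

    def test_cost_decrease_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("cheaper", cost_multiplier=0.5)

    def test_referral_override_touches_only_referral_rate(self, pset):
        sc = ScenarioSpec("ref80", referral_rate=0.8)
        out = sc.apply(pset)
        assert out["p_ref_high"] == 0.8
        assert out["p_selfref_low"] == pset.params["p_selfref_low"].base
        assert out["p_selfref_unscreened"] == pset.params["p_selfref_unscreened"].base

    def test_cost_multiplier_scales_treatment_costs_only(self, pset):
        sc = ScenarioSpec("plus50", cost_multiplier=1.5)
        out = sc.apply(pset)
        assert out["c_diag"] == pytest.approx(28.57 * 1.5)
        assert out["c_med"] == pytest.approx(185.75 * 1.5)
        assert out["c_psychother"] == pytest.approx(274.3 * 1.5)
        assert out["c_screen"] == pytest.approx(22.3)
        assert out["c_care"] == pytest.approx(480.0)

    def test_higher_treatment_costs_raise_screening_icer(self, pset):
        tables = run_scenarios(pset, [
            ScenarioSpec("base", cost_multiplier=1.0),
            ScenarioSpec("plus50", cost_multiplier=1.5),
            ScenarioSpec("plus100", cost_multiplier=2.0),
        ])
        icers = [
            tables[k][tables[k].strategy == SCREENING].iloc[0].icer
            for k in ("base", "plus50", "plus100")
        ]
        assert icers[0] < icers[1] < icers[2]
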