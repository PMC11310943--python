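import copy
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcscea.economics import UndefinedICERError
from lcscea.parameters import Scenario, ScenarioError, SpecialFlags, get_path
from lcscea.pipeline import run_model
from lcscea.sensitivity import (
    PsaSamples,
    ceac,
    one_way,
    probabilistic_icer,
    run_scenarios,
    sample_psa,
    standard_scenarios,
    tornado_frame,
    _draw_value,
)
from lcscea.parameters import DistributionSpec


def linear_runner(path, a, b, dq=100.0):
    """Toy model: delta cost is linear in one parameter, delta QALYs fixed."""

    def run(p):
        theta = get_path(p, path)
        return SimpleNamespace(delta_cost=a + b * theta, delta_qaly=dq, delta_ly=dq)

    return run


class TestOneWay:
    def test_linear_closed_form(self, base_params):
        path = "costs.ct_scan"
        theta = get_path(base_params, path)
        runner = linear_runner(path, a=1000.0, b=2.0)
        (entry,) = one_way(base_params, [path], delta=0.2, runner=runner)
        assert entry.icer_low == pytest.approx((1000 + 2 * 0.8 * theta) / 100.0)
        assert entry.icer_high == pytest.approx((1000 + 2 * 1.2 * theta) / 100.0)

    def test_inactive_parameter_has_zero_span(self, base_params):
        runner = linear_runner("costs.ct_scan", a=500.0, b=0.0)
        (entry,) = one_way(base_params, ["costs.stage.IV.year2"], runner=runner)
        assert entry.span == 0.0

    def test_sorted_by_span_descending(self, base_params):
        runner = linear_runner("costs.ct_scan", a=0.0, b=3.0)
        entries = one_way(base_params, ["costs.stage.IV.year2", "costs.ct_scan"], runner=runner)
        assert entries[0].parameter == "costs.ct_scan"
        assert entries[0].span >= entries[1].span

    def test_probability_capped_at_one(self, base_params):
        seen = []

        def runner(p):
            seen.append(get_path(p, "settings.adherence"))
            return SimpleNamespace(delta_cost=1.0, delta_qaly=1.0)

        one_way(base_params, ["settings.adherence"], delta=0.2, runner=runner)
        assert seen == [pytest.approx(0.8), 1.0]  # 1.2 capped

    def test_bad_path_raises(self, base_params):
        with pytest.raises(ScenarioError):
            one_way(base_params, ["nope.nope"], runner=lambda p: None)

    def test_bad_delta_raises(self, base_params):
        with pytest.raises(ValueError):
            one_way(base_params, ["costs.ct_scan"], delta=1.5, runner=lambda p: None)

    def test_frame_schema(self, base_params):
        runner = linear_runner("costs.ct_scan", a=0.0, b=1.0)
        frame = tornado_frame(one_way(base_params, ["costs.ct_scan"], runner=runner))
        assert list(frame.columns) == ["parameter", "icer_low", "icer_high", "span"]


class TestSamplePsa:
    def test_seed_reproducibility(self, base_params):
        runner = linear_runner("costs.ct_scan", a=0.0, b=1.0)
        a = sample_psa(base_params, 20, seed=9, runner=runner)
        b = sample_psa(base_params, 20, seed=9, runner=runner)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert a.parameters.equals(b.parameters)

    def test_gamma_moment_match(self):
        rng = np.random.default_rng(0)
        spec = DistributionSpec(kind="gamma", mean=280.0, se=56.0)
        draws = np.array([_draw_value(spec, rng) for _ in range(1000)])
        assert abs(draws.mean() - 280.0) < 3 * 56.0 / np.sqrt(1000)

    def test_beta_respects_bounds(self):
        rng = np.random.default_rng(1)
        spec = DistributionSpec(kind="beta", mean=0.78, se=0.156)
        draws = np.array([_draw_value(spec, rng) for _ in range(500)])
        assert np.all((draws > 0) & (draws < 1))
        assert abs(draws.mean() - 0.78) < 0.03

    def test_unparameterizable_beta_names_parameter(self, base_params):
        p = copy.deepcopy(base_params)
        p.distributions["settings.uptake"].se = 0.9  # variance too large
        with pytest.raises(ValueError, match="settings.uptake"):
            sample_psa(p, 2, seed=0, runner=lambda q: SimpleNamespace(delta_cost=0, delta_qaly=1))

    def test_degenerate_psa_equals_deterministic(self, base_params):
        p = copy.deepcopy(base_params)
        for spec in p.distributions.values():
            spec.se = 0.0
        det = run_model(p)
        samples = sample_psa(p, 3, seed=123)
        assert np.all(samples.delta_cost == det.delta_cost)
        assert np.all(samples.delta_qaly == det.delta_qaly)

    def test_dirichlet_group_draws_sum_to_one(self, base_params):
        captured = []

        def runner(q):
            captured.append(
                sum(q.epidemiology.clinical_stage_distribution[s] for s in "I II III IV".split())
            )
            return SimpleNamespace(delta_cost=0.0, delta_qaly=1.0)

        sample_psa(base_params, 5, seed=2, runner=runner)
        assert all(total == pytest.approx(1.0, abs=1e-9) for total in captured)


class TestProbabilisticIcer:
    def test_degenerate_samples(self):
        s = PsaSamples(
            np.full(10, 1_382_091_070.0), np.full(10, 56_122.0), pd.DataFrame(), None
        )
        assert probabilistic_icer(s) == pytest.approx(24_627, abs=1.0)

    def test_two_draws(self):
        s = PsaSamples(np.array([100.0, 300.0]), np.array([1.0, 1.0]), pd.DataFrame(), None)
        assert probabilistic_icer(s) == pytest.approx(200.0)

    def test_mean_of_ratios_option(self):
        s = PsaSamples(np.array([100.0, 300.0]), np.array([1.0, 2.0]), pd.DataFrame(), None)
        assert probabilistic_icer(s, method="mean_of_ratios") == pytest.approx(125.0)

    def test_zero_mean_effect_raises(self):
        s = PsaSamples(np.array([1.0, 1.0]), np.array([1.0, -1.0]), pd.DataFrame(), None)
        with pytest.raises(UndefinedICERError):
            probabilistic_icer(s)


class TestCeac:
    def test_brute_force_count(self):
        s = PsaSamples(np.array([100.0, 300.0, 500.0]), np.array([2.0, 2.0, 2.0]), pd.DataFrame(), None)
        out = ceac(s, [150.0])
        assert out["prob_cost_effective"].iloc[0] == pytest.approx(1 / 3)

    def test_lambda_zero_counts_cost_saving(self):
        s = PsaSamples(np.array([-5.0, 10.0]), np.array([1.0, 1.0]), pd.DataFrame(), None)
        assert ceac(s, [0.0])["prob_cost_effective"].iloc[0] == 0.5

    def test_all_below_threshold(self):
        s = PsaSamples(np.array([100.0, 200.0]), np.array([1.0, 1.0]), pd.DataFrame(), None)
        assert ceac(s, [1000.0])["prob_cost_effective"].iloc[0] == 1.0

    def test_empty_grid_rejected(self):
        s = PsaSamples(np.array([1.0]), np.array([1.0]), pd.DataFrame(), None)
        with pytest.raises(ValueError):
            ceac(s, [])

    @given(
        dc=st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=20),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_when_all_dq_positive(self, dc):
        dq = np.ones(len(dc))
        s = PsaSamples(np.array(dc), dq, pd.DataFrame(), None)
        probs = ceac(s, [0.0, 1e4, 1e5, 1e6])["prob_cost_effective"].to_numpy()
        assert np.all(np.diff(probs) >= 0)


class TestRunScenarios:
    def test_empty_scenario_matches_base(self, base_params, base_result):
        table = run_scenarios(base_params, [Scenario(name="base")])
        row = table.iloc[0]
        assert row["icer"] == base_result.icer_qaly
        assert row["delta_cost"] == pytest.approx(base_result.delta_cost)

    def test_ct82_lowers_icer(self, base_params, base_result):
        table = run_scenarios(base_params, [Scenario(name="ct82", overrides={"costs.ct_scan": 82.0})])
        assert table.iloc[0]["icer"] < base_result.icer_qaly
        # QALYs untouched by a pure cost override
        assert table.iloc[0]["delta_qalys"] == pytest.approx(base_result.delta_qaly)

    def test_fp_disutility_monotone(self, base_params):
        scenarios = [
            Scenario(name="du015", special_flags=SpecialFlags(fp_disutility=0.015)),
            Scenario(name="du05", special_flags=SpecialFlags(fp_disutility=0.05)),
        ]
        table = run_scenarios(base_params, scenarios)
        assert table.iloc[1]["delta_qalys"] < table.iloc[0]["delta_qalys"]
        assert table.iloc[1]["icer"] > table.iloc[0]["icer"]

    def test_zero_discount_lowers_icer(self, base_params, base_result):
        sc = Scenario(
            name="disc0",
            overrides={"settings.discount_rate_costs": 0.0, "settings.discount_rate_health": 0.0},
        )
        table = run_scenarios(base_params, [sc])
        assert table.iloc[0]["icer"] < base_result.icer_qaly

    def test_immunotherapy_uplift_lowers_incremental_treatment(self, base_params, base_result):
        sc = Scenario(name="immuno", special_flags=SpecialFlags(immunotherapy_uplift=0.5))
        res = run_model(
            __import__("lcscea.parameters", fromlist=["apply_scenario"]).apply_scenario(
                base_params, sc
            )
        )
        # both arms get costlier, but no-screening (late-stage heavy) more so
        assert res.delta_cost < base_result.delta_cost
        assert res.arms["screening"].total_cost > base_result.arms["screening"].total_cost

    def test_standard_scenarios_shape(self):
        scenarios = standard_scenarios()
        names = [s.name for s in scenarios]
        assert len(names) == len(set(names))
        assert any("CT scan" in n for n in names)
        assert any("background mortality" in n for n in names)
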