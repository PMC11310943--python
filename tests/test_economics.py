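import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcscea.cohort_tree import ARMS
from lcscea.economics import (
    ArmResult,
    UndefinedICERError,
    aggregate,
    discount,
    icer,
    nmb,
    qaly_stream,
    screening_program_costs,
    treatment_cost_stream,
)
from lcscea.markov_engine import CohortTrace
from lcscea.parameters import STAGES
from lcscea.pipeline import run_model


def make_trace(pre, post=None, prog=None, lc_death=None, n=None):
    """Hand-built trace from per-cycle-boundary occupancy vectors."""
    pre = np.asarray(pre, float)
    post = np.zeros_like(pre) if post is None else np.asarray(post, float)
    n_cycles = pre.size - 1
    n = n if n is not None else pre[0] + post[0]
    occ = np.zeros((pre.size, 4))
    occ[:, 0] = pre
    occ[:, 1] = post
    lc = np.zeros(n_cycles) if lc_death is None else np.asarray(lc_death, float)
    occ[:, 2] = np.concatenate([[0.0], np.cumsum(lc)])
    occ[:, 3] = n - occ[:, 0] - occ[:, 1] - occ[:, 2]
    return CohortTrace(
        occupancy=occ,
        prog_events=np.zeros(n_cycles) if prog is None else np.asarray(prog, float),
        lc_death_events=lc,
        other_death_events=np.zeros(n_cycles),
        entry_age=58.0,
        entry_year=0.0,
        cycle_length=0.25,
        stage="I",
        n=n,
    )


class TestDiscount:
    def test_one_year_five_percent(self):
        assert discount(100.0, 1.0, 0.05) == pytest.approx(95.238, abs=1e-3)

    def test_zero_rate_identity(self):
        assert discount(123.45, 7.0, 0.0) == 123.45

    def test_time_zero(self):
        assert discount(100.0, 0.0, 0.05) == 100.0

    def test_vectorized(self):
        out = discount(np.array([100.0, 100.0]), np.array([0.0, 1.0]), 0.05)
        assert out[0] == 100.0 and out[1] == pytest.approx(100 / 1.05)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            discount(1.0, -1.0, 0.05)
        with pytest.raises(ValueError):
            discount(1.0, 1.0, -0.05)

    @given(rates=st.lists(st.floats(0.0, 0.2), min_size=2, max_size=2, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_rate(self, rates):
        lo, hi = sorted(rates)
        if hi - lo < 1e-9:
            return
        stream = np.ones(10)
        times = np.arange(1, 11, dtype=float)
        assert discount(stream, times, hi).sum() < discount(stream, times, lo).sum()


class TestIcerNmb:
    def test_base_case_icer(self):
        assert icer(1_382_091_070, 56_122) == 24_627

    def test_life_year_icer(self):
        assert icer(1_382_091_070, 84_049) == 16_444

    def test_zero_cost(self):
        assert icer(0.0, 10.0) == 0

    def test_zero_effect_raises(self):
        with pytest.raises(UndefinedICERError):
            icer(100.0, 0.0)

    @given(k=st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, k):
        assert icer(k * 1_000_000.0, k * 100.0) == icer(1_000_000.0, 100.0)

    def test_nmb_base_case(self):
        value = nmb(50_000, 56_122, 1_382_091_070)
        assert value == 1_424_008_930
        # rounded inputs land within 1e-5 relative of the unrounded original
        assert value == pytest.approx(1_424_012_194, rel=1e-5)

    def test_nmb_trivial(self):
        assert nmb(12345, 0.0, 0.0) == 0.0
        assert nmb(0.0, 10.0, 250.0) == -250.0

    def test_nmb_sign_matches_icer_vs_wtp(self):
        assert nmb(50_000, 10.0, 400_000) > 0 and icer(400_000, 10.0) < 50_000
        assert nmb(50_000, 10.0, 600_000) < 0 and icer(600_000, 10.0) > 50_000


class TestTreatmentCostStream:
    def test_stage_i_first_year_progression_free(self, base_params):
        # alive pre-progression through cycles 0-3, then gone
        trace = make_trace([1, 1, 1, 1, 0, 0, 0, 0, 0])
        stream = treatment_cost_stream(trace, "I", base_params.costs)
        # 8564 entry + 1956 over cycles 1-3 + one follow-up visit at cycle 2
        visit = base_params.costs.followup_ct + base_params.costs.followup_consult
        assert stream[:4].sum() == pytest.approx(8564 + 1956 + visit)
        assert visit == 280 + 88

    def test_death_in_first_cycle(self, base_params):
        trace = make_trace([1, 0, 0], lc_death=[1, 0])
        stream = treatment_cost_stream(trace, "I", base_params.costs)
        assert stream[0] == pytest.approx(8564 + 7466)

    def test_second_line_on_progression_event(self, base_params):
        trace = make_trace([1, 0, 0], post=[0, 1, 1], prog=[1, 0])
        stream = treatment_cost_stream(trace, "I", base_params.costs)
        assert stream[0] == pytest.approx(8564 + 32_085)

    def test_zero_person_trace(self, base_params):
        trace = make_trace([0, 0, 0])
        assert treatment_cost_stream(trace, "I", base_params.costs).sum() == 0.0


class TestQalyStream:
    def test_pre_progression_person_year(self, base_params):
        trace = make_trace([1, 1, 1, 1, 1])
        assert qaly_stream(trace, base_params.utilities, "I").sum() == pytest.approx(0.78)

    def test_post_progression_person_year(self, base_params):
        trace = make_trace([0, 0, 0, 0, 0], post=[1, 1, 1, 1, 1], n=1.0)
        for st_key in STAGES:
            assert qaly_stream(trace, base_params.utilities, st_key).sum() == pytest.approx(0.69)

    def test_unit_utility_gives_person_time(self, base_params):
        u = copy.deepcopy(base_params.utilities)
        u.pre_progression = {s: 1.0 for s in STAGES}
        u.post_progression = {s: 1.0 for s in STAGES}
        trace = make_trace([1, 1, 1, 1, 1])
        assert qaly_stream(trace, u, "II").sum() == pytest.approx(1.0)


class TestScreeningProgramCosts:
    def test_single_round_arithmetic(self, base_ledger, base_params):
        ledger = copy.deepcopy(base_ledger)
        ledger.screens = np.array([1000.0])
        ledger.false_positives = np.array([0.0])
        ledger.indeterminates = np.array([0.0])
        s = copy.deepcopy(base_params.settings)
        s.discount_rate_costs = 0.0
        out = screening_program_costs(ledger, base_params.costs, s)
        assert out["screening"] == pytest.approx(280_000.0)

    def test_recruitment_components(self, base_ledger, base_params):
        out = screening_program_costs(base_ledger, base_params.costs, base_params.settings)
        expected = base_ledger.invitation_letters * 3 + base_ledger.gp_consults * 22
        assert out["recruitment"] == pytest.approx(expected)

    def test_no_participants_means_letters_only(self, base_ledger, base_params):
        ledger = copy.deepcopy(base_ledger)
        ledger.gp_consults = 0
        out = screening_program_costs(ledger, base_params.costs, base_params.settings)
        assert out["recruitment"] == pytest.approx(ledger.invitation_letters * 3)

    def test_no_attrition_upper_bound(self, base_result):
        # 280 * 300,277 * sum_{k=0..16} 1.05^-k, derived independently
        bound = 280 * 300_277 * sum(1.05**-k for k in range(17))
        assert bound == pytest.approx(995.29e6, rel=1e-3)
        assert base_result.arms["screening"].screening <= bound


class TestAggregate:
    def _arm(self, total_qalys, treat):
        return ArmResult(
            lys=total_qalys * 1.2,
            qalys=total_qalys,
            treatment_by_stage={"I": treat, "II": 0.0, "III": 0.0, "IV": 0.0},
        )

    def test_identical_arms_all_zero(self, base_params):
        arms = {a: self._arm(100.0, 5000.0) for a in ARMS}
        res = aggregate(arms, base_params.settings)
        assert res.delta_cost == res.delta_qaly == res.delta_ly == 0.0
        assert res.icer_qaly is None
        assert res.dominance == "identical effects"
        assert res.nmb == 0.0

    def test_printed_incrementals_reproduce_icer(self, base_params):
        arms = {
            "screening": self._arm(56_122.0, 1_382_091_070.0),
            "no_screening": self._arm(0.0, 0.0),
        }
        res = aggregate(arms, base_params.settings)
        assert res.icer_qaly == 24_627

    def test_mismatched_arms_rejected(self, base_params):
        with pytest.raises(ValueError):
            aggregate({"screening": ArmResult()}, base_params.settings)


class TestEndToEnd:
    def test_category_completeness(self, base_result):
        for arm in base_result.arms.values():
            total = (
                arm.recruitment + arm.screening + arm.diagnostic + arm.treatment + arm.end_of_life
            )
            assert abs(arm.total_cost - total) <= 1.0

    def test_stage_iv_treatment_incremental_negative(self, base_result):
        s = base_result.arms["screening"].treatment_by_stage["IV"]
        n = base_result.arms["no_screening"].treatment_by_stage["IV"]
        assert s < n  # screening shifts stage IV mass down

    def test_nmb_sign_consistent(self, base_result):
        assert base_result.delta_qaly > 0
        assert (base_result.nmb > 0) == (base_result.icer_qaly < base_result.wtp)

    def test_uptake_zero_exact_null(self, base_params):
        p = copy.deepcopy(base_params)
        p.settings.uptake = 0.0
        res = run_model(p)
        assert res.delta_cost == 0.0
        assert res.delta_qaly == 0.0
        assert res.delta_ly == 0.0

    def test_zero_discount_exceeds_discounted(self, base_params, base_result):
        p = copy.deepcopy(base_params)
        p.settings.discount_rate_costs = 0.0
        p.settings.discount_rate_health = 0.0
        res0 = run_model(p)
        assert res0.arms["screening"].total_cost > base_result.arms["screening"].total_cost
        assert res0.arms["screening"].qalys > base_result.arms["screening"].qalys

    def test_result_json_round_trip(self, base_result):
        import json

        data = json.loads(base_result.to_json())
        assert data["icer_qaly"] == base_result.icer_qaly
        assert set(data["arms"]) == set(ARMS)
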