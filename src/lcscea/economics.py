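"""Discounting, cost and utility streams, and arm-level / incremental results.

Conventions: discounting is anchored to program start (year 0, the first
screening round).  Costs are billed at the start of the cycle in which they
accrue; person-time and QALYs are credited at the end of each cycle (no
half-cycle correction).  Accrual stops at the accumulation horizon; state
transitions do not.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from lcscea.cohort_tree import ARMS, DiagnosisLedger
from lcscea.markov_engine import (
    STATE_POST,
    STATE_PRE,
    CohortTrace,
    LIFETIME_YEARS,
    run_cohort_batch,
)
from lcscea.parameters import MISSED, STAGES, ParameterSet
from lcscea.synthetic_data import LifeTable

COST_CATEGORIES = ("recruitment", "screening", "diagnostic", "treatment", "end_of_life")


class UndefinedICERError(ZeroDivisionError):
    """Incremental effect is zero: report dominance, not a ratio."""


def discount(value, t, rate: float):
    """Present value of ``value`` accruing at time ``t`` years (cycle-start
    convention, no midpoint correction)."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = np.asarray(value, dtype=float) / (1.0 + rate) ** t
    return float(out) if out.ndim == 0 else out


def icer(delta_cost: float, delta_effect: float) -> int:
    """Incremental cost-effectiveness ratio, rounded to whole EUR."""
    if delta_effect == 0:
        raise UndefinedICERError("incremental effect is zero")
    return int(round(delta_cost / delta_effect))


def nmb(wtp: float, delta_q: float, delta_c: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    return wtp * delta_q - delta_c


# ---------------------------------------------------------------------------
# per-stratum streams

#: follow-up visit cycles: twice-yearly in the first two years, then annual
def _followup_cycles(n_cycles: int):
    sched = [k for k in (2, 4, 6, 8) if k < n_cycles]
    sched += list(range(12, n_cycles, 4))
    return sched


def _per_cycle_schedule(cs, stage: str, n_cycles: int) -> np.ndarray:
    """EUR billed per alive pre-progression person at the start of each cycle
    (first-line phases and aftercare visits; event costs excluded)."""
    sc = cs.stage[stage]
    sched = np.zeros(n_cycles)
    sched[1 : min(4, n_cycles)] += sc.rest_of_year1 / 3.0
    sched[4 : min(8, n_cycles)] += sc.year2 / 4.0
    visit = cs.followup_ct + cs.followup_consult
    for k in _followup_cycles(n_cycles):
        sched[k] += visit
    return sched


def treatment_cost_stream(trace: CohortTrace, stage: str, cs) -> np.ndarray:
    """Undiscounted treatment + aftercare + end-of-life EUR per cycle."""
    n_cycles = trace.n_cycles
    sc = cs.stage[stage]
    out = np.zeros(n_cycles)
    pre = trace.occupancy[:-1, STATE_PRE]
    out += _per_cycle_schedule(cs, stage, n_cycles) * pre
    if n_cycles:
        out[0] += sc.first_3_months * trace.occupancy[0, STATE_PRE]
    out += sc.second_line * trace.prog_events
    out += cs.end_of_life * trace.lc_death_events
    return out


def qaly_stream(trace: CohortTrace, u, stage: str) -> np.ndarray:
    """Undiscounted QALYs per cycle for a diagnosed stratum."""
    dt = trace.cycle_length
    pre = trace.occupancy[1:, STATE_PRE]
    post = trace.occupancy[1:, STATE_POST]
    return (pre * u.pre_progression[stage] + post * u.post_progression[stage]) * dt


def screening_program_costs(
    ledger: DiagnosisLedger, cs, settings, arm: str = "screening"
) -> Dict[str, float]:
    """Discounted recruitment, screening and diagnostic costs for one arm.

    Recruitment (invitation letters for everyone aged 50-74 plus one GP
    consult per participant) falls at program start, undiscounted.  Screening
    bills one CT per performed screen at its round year; diagnostics bill
    per screen-positive (true or false) and per clinical presenter.
    """
    rc = settings.discount_rate_costs
    horizon = settings.horizon
    if arm == "screening":
        recruitment = (
            ledger.invitation_letters * cs.invitation_letter
            + ledger.gp_consults * cs.gp_consult
        )
        rounds = np.arange(ledger.screens.size)
        mask = rounds < horizon
        screening = float(
            np.sum(discount(ledger.screens[mask] * cs.ct_scan, rounds[mask], rc))
        )
        diagnostic = float(
            np.sum(
                discount(ledger.false_positives[mask] * cs.diag_screen_detected, rounds[mask], rc)
            )
        )
        for st in STAGES:
            for year, mass in ledger.screen_detected[st].items():
                if year < horizon:
                    diagnostic += discount(mass * cs.diag_screen_detected, year, rc)
    else:
        recruitment = 0.0
        screening = 0.0
        diagnostic = 0.0
    for st in STAGES:
        for year, mass in ledger.clinical[arm][st].items():
            if 0 <= year < horizon:
                diagnostic += discount(mass * cs.diag_clinical, year, rc)
    return {"recruitment": recruitment, "screening": screening, "diagnostic": diagnostic}


# ---------------------------------------------------------------------------
# results


@dataclass
class ArmResult:
    lys: float = 0.0
    qalys: float = 0.0
    lys_by_group: Dict[str, float] = field(default_factory=dict)
    qalys_by_group: Dict[str, float] = field(default_factory=dict)
    diagnoses_by_stage: Dict[str, float] = field(default_factory=dict)
    missed_count: float = 0.0
    lc_deaths_by_group: Dict[str, float] = field(default_factory=dict)
    recruitment: float = 0.0
    screening: float = 0.0
    diagnostic: float = 0.0
    treatment_by_stage: Dict[str, float] = field(default_factory=dict)
    end_of_life: float = 0.0

    @property
    def treatment(self) -> float:
        return sum(self.treatment_by_stage.values())

    @property
    def total_cost(self) -> float:
        return self.recruitment + self.screening + self.diagnostic + self.treatment + self.end_of_life

    @property
    def lc_deaths(self) -> float:
        return sum(self.lc_deaths_by_group.values())


@dataclass
class EconomicResult:
    arms: Dict[str, ArmResult]
    wtp: float
    delta_cost: float = 0.0
    delta_ly: float = 0.0
    delta_qaly: float = 0.0
    icer_qaly: Optional[int] = None
    icer_ly: Optional[int] = None
    nmb: float = 0.0
    dominance: Optional[str] = None

    def to_dict(self) -> dict:
        def arm_dict(a: ArmResult) -> dict:
            return {
                "lys": a.lys,
                "qalys": a.qalys,
                "lys_by_group": a.lys_by_group,
                "qalys_by_group": a.qalys_by_group,
                "diagnoses_by_stage": a.diagnoses_by_stage,
                "missed_count": a.missed_count,
                "lc_deaths_by_group": a.lc_deaths_by_group,
                "costs": {
                    "recruitment": a.recruitment,
                    "screening": a.screening,
                    "diagnostic": a.diagnostic,
                    "treatment_by_stage": a.treatment_by_stage,
                    "end_of_life": a.end_of_life,
                    "total": a.total_cost,
                },
            }

        return {
            "schema_version": 1,
            "arms": {arm: arm_dict(a) for arm, a in self.arms.items()},
            "incremental": {
                "cost": self.delta_cost,
                "lys": self.delta_ly,
                "qalys": self.delta_qaly,
            },
            "icer_qaly": self.icer_qaly,
            "icer_ly": self.icer_ly,
            "nmb": self.nmb,
            "wtp": self.wtp,
            "dominance": self.dominance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def aggregate(arms: Dict[str, ArmResult], settings) -> EconomicResult:
    """Combine the two arm results into incremental outputs."""
    if set(arms) != set(ARMS):
        raise ValueError(f"expected arms {ARMS}, got {tuple(arms)}")
    s, n = arms["screening"], arms["no_screening"]
    for a in arms.values():
        for name in ("recruitment", "screening", "diagnostic", "end_of_life"):
            if getattr(a, name) < 0:
                raise ValueError(f"negative {name} cost component")
    res = EconomicResult(
        arms=arms,
        wtp=settings.wtp,
        delta_cost=s.total_cost - n.total_cost,
        delta_ly=s.lys - n.lys,
        delta_qaly=s.qalys - n.qalys,
    )
    try:
        res.icer_qaly = icer(res.delta_cost, res.delta_qaly)
    except UndefinedICERError:
        res.dominance = "identical effects" if res.delta_cost == 0 else "undefined (zero QALY difference)"
    try:
        res.icer_ly = icer(res.delta_cost, res.delta_ly)
    except UndefinedICERError:
        res.icer_ly = None
    res.nmb = nmb(settings.wtp, res.delta_qaly, res.delta_cost)
    return res


# ---------------------------------------------------------------------------
# full evaluation of a diagnosis ledger


def evaluate(
    ledger: DiagnosisLedger,
    curves: dict,
    lt: LifeTable,
    p: ParameterSet,
) -> EconomicResult:
    """Run every diagnosed stratum through the Markov engine, accumulate
    discounted cost/utility streams and aggregate both arms."""
    s = p.settings
    dt = s.cycle_length
    horizon = s.horizon
    rc, rh = s.discount_rate_costs, s.discount_rate_health
    bg_mult = p.background_mortality_multiplier
    flags = p.special_flags

    cs = p.costs
    if flags.immunotherapy_uplift:
        cs = cs.model_copy(deep=True)
        scale = 1.0 + flags.immunotherapy_uplift * flags.immunotherapy_cost_share
        for st in ("III", "IV"):
            cs.stage[st].first_3_months *= scale
            cs.stage[st].rest_of_year1 *= scale
            cs.stage[st].year2 *= scale

    # Death hazard from both living states follows the stratum's own OS
    # curve, so the engine's alive fraction reproduces the fitted OS anchors.
    n_cycles = int(round(LIFETIME_YEARS / dt))
    cycle_end = (np.arange(n_cycles) + 1) * dt  # time since entry, end of cycle
    cycle_start = np.arange(n_cycles) * dt

    # strata: (group, stage_key, arm(s), pathway) masses by entry year
    strata: Dict[str, list] = {key: [] for key in (*STAGES, MISSED)}

    def push(stage_key, entry_year, mass, arms, group, costed_stage=None):
        strata[stage_key].append((entry_year, mass, arms, group, costed_stage))

    for st in STAGES:
        for year, mass in ledger.screen_detected[st].items():
            push(st, year, mass, ("screening",), st, st)
        for arm in ARMS:
            for year, mass in ledger.clinical[arm][st].items():
                push(st, year, mass, (arm,), st, st)
    for year, mass in ledger.missed.items():
        push(MISSED, year, mass, ("no_screening",), MISSED, None)
    for year, mass in ledger.residual.items():
        push(MISSED, year, mass, ARMS, "residual", None)

    arms = {arm: ArmResult() for arm in ARMS}
    for arm in arms.values():
        arm.treatment_by_stage = {st: 0.0 for st in STAGES}
        for group in (*STAGES, MISSED, "residual", "cancer_free"):
            arm.lys_by_group[group] = 0.0
            arm.qalys_by_group[group] = 0.0
            arm.lc_deaths_by_group.setdefault(group, 0.0)

    pop_util = p.utilities.population_utility_by_age
    max_age = max(pop_util) if pop_util else 110

    def pop_utility_at(ages: np.ndarray) -> np.ndarray:
        idx = np.clip(np.floor(ages).astype(int), min(pop_util), max_age)
        return np.array([pop_util[a] for a in idx])

    for stage_key, entries in strata.items():
        if not entries:
            continue
        entry_years = sorted({e[0] for e in entries})
        ey_index = {y: i for i, y in enumerate(entry_years)}
        occ, prog, lc_death, other_death = run_cohort_batch(
            stage_key,
            np.array(entry_years, dtype=float),
            ledger.entry_age,
            curves[stage_key],
            lt,
            cycle_length=dt,
            years=LIFETIME_YEARS,
            bg_mult=bg_mult,
        )
        for i, ey in enumerate(entry_years):
            t_end = ey + cycle_end  # calendar time, program clock
            t_start = ey + cycle_start
            m_accr = (t_end > 0) & (t_end <= horizon)
            m_cost = (t_start >= 0) & (t_start < horizon)
            df_h_end = 1.0 / (1.0 + rh) ** np.maximum(t_end, 0.0)
            df_c_start = 1.0 / (1.0 + rc) ** np.maximum(t_start, 0.0)

            alive = occ[i, 1:, STATE_PRE] + occ[i, 1:, STATE_POST]
            unit_ly = float(np.sum(alive * dt * df_h_end * m_accr))
            if stage_key == MISSED:
                ages = ledger.entry_age + t_end
                util = pop_utility_at(ages)
                unit_q = float(np.sum(alive * util * dt * df_h_end * m_accr))
            else:
                u = p.utilities
                q_raw = (
                    occ[i, 1:, STATE_PRE] * u.pre_progression[stage_key]
                    + occ[i, 1:, STATE_POST] * u.post_progression[stage_key]
                ) * dt
                unit_q = float(np.sum(q_raw * df_h_end * m_accr))
            unit_deaths = float(np.sum(lc_death[i] * m_accr))

            for entry_year, mass, arm_names, group, costed_stage in entries:
                if entry_year != ey:
                    continue
                if costed_stage is not None:
                    sched = _per_cycle_schedule(cs, costed_stage, n_cycles)
                    treat = sched * occ[i, :-1, STATE_PRE]
                    treat[0] += cs.stage[costed_stage].first_3_months
                    treat += cs.stage[costed_stage].second_line * prog[i]
                    unit_treat = float(np.sum(treat * df_c_start * m_cost))
                    unit_eol = float(
                        np.sum(cs.end_of_life * lc_death[i] * df_c_start * m_cost)
                    )
                else:
                    unit_treat = 0.0
                    unit_eol = 0.0
                for arm_name in arm_names:
                    arm = arms[arm_name]
                    arm.lys += mass * unit_ly
                    arm.qalys += mass * unit_q
                    arm.lys_by_group[group] += mass * unit_ly
                    arm.qalys_by_group[group] += mass * unit_q
                    arm.lc_deaths_by_group[group] += mass * unit_deaths
                    if costed_stage is not None:
                        arm.treatment_by_stage[costed_stage] += mass * unit_treat
                        arm.end_of_life += mass * unit_eol

    # lung-cancer-free mass: identical in both arms
    cf = ledger.cancer_free_by_year
    cf_ly = cf_q = 0.0
    for y in range(min(len(cf) - 1, int(math.ceil(horizon)))):
        q_bg = 1.0 - math.exp(-bg_mult * -math.log1p(-min(lt.q(ledger.entry_age + y), 1.0 - 1e-12)))
        h = -math.log1p(-q_bg) if q_bg < 1 else 50.0
        for j in range(int(round(1.0 / dt))):
            t = y + (j + 1) * dt
            if t > horizon:
                break
            m = cf[y] * math.exp(-h * (j + 1) * dt)
            dfh = 1.0 / (1.0 + rh) ** t
            cf_ly += m * dt * dfh
            cf_q += m * dt * dfh * pop_util[min(int(ledger.entry_age + t), max_age)]
    for arm in arms.values():
        arm.lys += cf_ly
        arm.qalys += cf_q
        arm.lys_by_group["cancer_free"] += cf_ly
        arm.qalys_by_group["cancer_free"] += cf_q

    # program costs and diagnoses
    for arm_name in ARMS:
        prog_costs = screening_program_costs(ledger, cs, s, arm=arm_name)
        arms[arm_name].recruitment = prog_costs["recruitment"]
        arms[arm_name].screening = prog_costs["screening"]
        arms[arm_name].diagnostic = prog_costs["diagnostic"]
        arms[arm_name].diagnoses_by_stage = ledger.diagnoses_by_stage(arm_name)
    arms["no_screening"].missed_count = sum(ledger.missed.values())
    if flags.smoking_cessation_cost:
        arms["screening"].recruitment += flags.smoking_cessation_cost * ledger.n_participants

    # scenario disutility for false-positive / indeterminate screens
    if flags.fp_disutility:
        rounds = np.arange(ledger.screens.size)
        mask = rounds < horizon
        affected = ledger.false_positives + ledger.indeterminates
        loss = float(np.sum(discount(affected[mask] * flags.fp_disutility, rounds[mask], rh)))
        arms["screening"].qalys -= loss
        arms["screening"].qalys_by_group["cancer_free"] -= loss

    return aggregate(arms, s)
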