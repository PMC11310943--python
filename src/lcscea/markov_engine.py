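"""Stage-stratified cohort state-transition engine at three-month cycles.

States: pre-progression, post-progression, dead (lung cancer), dead (other
cause).  The deterministic cohort engine propagates continuous person mass;
a per-individual microsimulation with identical matrices serves as a testing
oracle.  Person-time is credited at the end of each cycle (no half-cycle
correction; an optional flag enables it for sensitivity checks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from lcscea.survival import (
    FittedCurve,
    HAZARD_CAP,
    cumulative_hazard,
    cycle_matrix,
    life_table_hazard,
)

STATE_PRE, STATE_POST, STATE_DEAD_LC, STATE_DEAD_OTHER = range(4)

#: patient lifetime; transitions always run this long from diagnosis
LIFETIME_YEARS = 42.0

_EXTINCT = 1e-9


@dataclass
class CohortTrace:
    """State occupancy and transition events for one stratum."""

    occupancy: np.ndarray  # (n_cycles + 1, 4)
    prog_events: np.ndarray  # (n_cycles,) pre -> post mass per cycle
    lc_death_events: np.ndarray
    other_death_events: np.ndarray
    entry_age: float
    entry_year: float
    cycle_length: float
    stage: str
    n: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self) -> np.ndarray:
        return self.occupancy[:, STATE_PRE] + self.occupancy[:, STATE_POST]

    def to_frame(self):
        """Tidy export: (stratum, cycle, state, occupancy)."""
        import pandas as pd

        labels = ("pre_progression", "post_progression", "dead_lc", "dead_other")
        stratum = f"{self.stage}@{self.entry_year:g}"
        rows = [
            (stratum, k, label, self.occupancy[k, j])
            for k in range(self.occupancy.shape[0])
            for j, label in enumerate(labels)
        ]
        return pd.DataFrame(rows, columns=["stratum", "cycle", "state", "occupancy"])

    def check_invariants(self, atol: float = 1e-9) -> None:
        occ = self.occupancy
        if np.any(occ < -atol):
            raise AssertionError("negative occupancy")
        totals = occ.sum(axis=1)
        if np.any(np.abs(totals - self.n) > max(atol, atol * self.n)):
            raise AssertionError("person mass not conserved across cycles")
        for col in (STATE_DEAD_LC, STATE_DEAD_OTHER):
            if np.any(np.diff(occ[:, col]) < -atol):
                raise AssertionError("dead-state occupancy decreased")


def run_cohort(
    stage: str,
    n: float,
    entry_age: float,
    entry_year: float,
    curves: dict,
    lt,
    cycle_length: float = 0.25,
    years: float = LIFETIME_YEARS,
    bg_mult: float = 1.0,
    post_os: Optional[FittedCurve] = None,
) -> CohortTrace:
    """Propagate one stratum through the Markov model until ``years`` after
    entry or extinction.  All persons start in pre-progression."""
    if n < 0:
        raise ValueError("person mass must be non-negative")
    n_cycles = max(0, int(round(years / cycle_length)))
    occ = np.zeros((n_cycles + 1, 4))
    occ[0, STATE_PRE] = n
    prog = np.zeros(n_cycles)
    lc_death = np.zeros(n_cycles)
    other_death = np.zeros(n_cycles)
    os_curve, dpfs_curve = curves["os"], curves.get("dpfs")
    for k in range(n_cycles):
        t = k * cycle_length
        if occ[k, STATE_PRE] + occ[k, STATE_POST] < _EXTINCT * max(n, 1.0):
            occ[k + 1 :] = occ[k]
            break
        tm = cycle_matrix(
            os_curve,
            dpfs_curve,
            lt,
            entry_age + t,
            t,
            cycle_length,
            bg_mult=bg_mult,
            post_os=post_os,
        )
        pre, post = occ[k, STATE_PRE], occ[k, STATE_POST]
        m = tm.matrix
        d_pre = pre * m[0, 2]
        d_post = post * m[1, 2]
        prog[k] = pre * m[0, 1]
        lc_death[k] = d_pre * tm.lc_share_pre + d_post * tm.lc_share_post
        other_death[k] = d_pre + d_post - lc_death[k]
        occ[k + 1, STATE_PRE] = pre * m[0, 0]
        occ[k + 1, STATE_POST] = prog[k] + post * m[1, 1]
        occ[k + 1, STATE_DEAD_LC] = occ[k, STATE_DEAD_LC] + lc_death[k]
        occ[k + 1, STATE_DEAD_OTHER] = occ[k, STATE_DEAD_OTHER] + other_death[k]
    trace = CohortTrace(
        occ, prog, lc_death, other_death, entry_age, entry_year, cycle_length, stage, n
    )
    trace.check_invariants(atol=1e-9 * max(n, 1.0))
    return trace


def trace_person_time(trace: CohortTrace, cycle_length: Optional[float] = None) -> np.ndarray:
    """Undiscounted life-years per cycle (end-of-cycle occupancy convention)."""
    dt = cycle_length if cycle_length is not None else trace.cycle_length
    return trace.alive()[1:] * dt


def microsim_oracle(
    stage: str,
    n_individuals: int,
    entry_age: float,
    entry_year: float,
    curves: dict,
    lt,
    seed: int,
    cycle_length: float = 0.25,
    years: float = LIFETIME_YEARS,
    bg_mult: float = 1.0,
    post_os: Optional[FittedCurve] = None,
) -> CohortTrace:
    """Individual-level simulation with the same per-cycle matrices."""
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    rng = np.random.default_rng(seed)
    n_cycles = max(0, int(round(years / cycle_length)))
    states = np.full(n_individuals, STATE_PRE, dtype=np.int8)
    occ = np.zeros((n_cycles + 1, 4))
    prog = np.zeros(n_cycles)
    lc_death = np.zeros(n_cycles)
    other_death = np.zeros(n_cycles)
    for st in range(4):
        occ[0, st] = np.count_nonzero(states == st)
    os_curve, dpfs_curve = curves["os"], curves.get("dpfs")
    for k in range(n_cycles):
        t = k * cycle_length
        alive = (states == STATE_PRE) | (states == STATE_POST)
        if not np.any(alive):
            occ[k + 1 :] = occ[k]
            break
        tm = cycle_matrix(
            os_curve, dpfs_curve, lt, entry_age + t, t, cycle_length,
            bg_mult=bg_mult, post_os=post_os,
        )
        m = tm.matrix
        u = rng.random(n_individuals)
        cause = rng.random(n_individuals)

        pre = states == STATE_PRE
        die = pre & (u < m[0, 2])
        progressing = pre & ~die & (u < m[0, 2] + m[0, 1])
        lc = die & (cause < tm.lc_share_pre)
        states[die & lc] = STATE_DEAD_LC
        states[die & ~lc] = STATE_DEAD_OTHER
        states[progressing] = STATE_POST
        n_die_pre_lc = np.count_nonzero(die & lc)
        n_die_pre_other = np.count_nonzero(die & ~lc)
        prog[k] = np.count_nonzero(progressing)

        post = (states == STATE_POST) & ~progressing  # progressed earlier
        die_post = post & (u < m[1, 2])
        lc_post = die_post & (cause < tm.lc_share_post)
        states[die_post & lc_post] = STATE_DEAD_LC
        states[die_post & ~lc_post] = STATE_DEAD_OTHER
        lc_death[k] = n_die_pre_lc + np.count_nonzero(die_post & lc_post)
        other_death[k] = n_die_pre_other + np.count_nonzero(die_post & ~lc_post)
        for st in range(4):
            occ[k + 1, st] = np.count_nonzero(states == st)
    trace = CohortTrace(
        occ, prog, lc_death, other_death, entry_age, entry_year, cycle_length,
        stage, float(n_individuals),
    )
    trace.check_invariants(atol=1e-6 * n_individuals)
    return trace


def run_cohort_batch(
    stage: str,
    entry_years: np.ndarray,
    base_entry_age: float,
    curves: dict,
    lt,
    cycle_length: float = 0.25,
    years: float = LIFETIME_YEARS,
    bg_mult: float = 1.0,
    post_os: Optional[FittedCurve] = None,
):
    """Unit-mass traces for many entry years at once (pipeline fast path).

    All strata share the disease hazards (functions of time since entry);
    only the background hazard differs through age.  Returns
    ``(occupancy, prog_events, lc_deaths, other_deaths)`` with leading
    dimension ``len(entry_years)``; equivalent to calling :func:`run_cohort`
    per entry year with n=1.
    """
    entry_years = np.asarray(entry_years, dtype=float)
    n_strata = entry_years.size
    n_cycles = max(0, int(round(years / cycle_length)))
    os_curve, dpfs_curve = curves["os"], curves.get("dpfs")
    grid = np.arange(n_cycles + 1) * cycle_length

    def interval_rate(curve):
        if curve is None:
            return np.zeros(n_cycles)
        ch = cumulative_hazard(curve, grid)
        return np.minimum(np.diff(ch) / cycle_length, HAZARD_CAP)

    lam_d = interval_rate(os_curve)
    mu_e = np.maximum(0.0, interval_rate(dpfs_curve) - lam_d) if dpfs_curve is not None else np.zeros(n_cycles)
    lam_post = interval_rate(post_os or os_curve)

    occ = np.zeros((n_strata, n_cycles + 1, 4))
    occ[:, 0, STATE_PRE] = 1.0
    prog = np.zeros((n_strata, n_cycles))
    lc_death = np.zeros((n_strata, n_cycles))
    other_death = np.zeros((n_strata, n_cycles))
    ages = base_entry_age + entry_years  # age at entry per stratum
    if lt is not None and n_strata:
        amin = int(math.floor(ages.min()))
        amax = int(math.floor(ages.max() + years)) + 1
        haz_table = np.array([life_table_hazard(lt, a) for a in range(amin, amax + 1)])
    for k in range(n_cycles):
        age_k = ages + k * cycle_length
        if lt is not None and n_strata:
            idx = np.clip(np.floor(age_k).astype(int) - amin, 0, haz_table.size - 1)
            lam_b = bg_mult * haz_table[idx]
        else:
            lam_b = np.zeros(n_strata)
        tot_pre = lam_d[k] + lam_b
        p_die_pre = -np.expm1(-tot_pre * cycle_length)
        p_prog = np.exp(-tot_pre * cycle_length) * (-math.expm1(-mu_e[k] * cycle_length))
        tot_post = lam_post[k] + lam_b
        p_die_post = -np.expm1(-tot_post * cycle_length)
        share_pre = np.divide(lam_d[k], tot_pre, out=np.zeros(n_strata), where=tot_pre > 0)
        share_post = np.divide(lam_post[k], tot_post, out=np.zeros(n_strata), where=tot_post > 0)

        pre = occ[:, k, STATE_PRE]
        post = occ[:, k, STATE_POST]
        d_pre = pre * p_die_pre
        d_post = post * p_die_post
        prog[:, k] = pre * p_prog
        lc_death[:, k] = d_pre * share_pre + d_post * share_post
        other_death[:, k] = d_pre + d_post - lc_death[:, k]
        occ[:, k + 1, STATE_PRE] = pre * (1.0 - p_die_pre - p_prog)
        occ[:, k + 1, STATE_POST] = prog[:, k] + post * (1.0 - p_die_post)
        occ[:, k + 1, STATE_DEAD_LC] = occ[:, k, STATE_DEAD_LC] + lc_death[:, k]
        occ[:, k + 1, STATE_DEAD_OTHER] = occ[:, k, STATE_DEAD_OTHER] + other_death[:, k]
    return occ, prog, lc_death, other_death
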