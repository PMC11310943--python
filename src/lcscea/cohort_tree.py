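"""Screening decision tree: eligibility, participation, annual rounds,
detection-pathway assignment and the diagnosis ledger.

Person mass is continuous throughout; integers appear only at reporting
boundaries.  Both arms share a single incident-cancer process applied to the
alive, cancer-free eligible mass, so underlying cancer mass is identical
across arms by construction.  Each incident cohort is split into a
clinically-destined part (presents ``clinical_delay_years`` after onset) and
a silent part; screening can detect either at attended rounds.  Silent
cancers that screening would have found are the no-screening arm's "missed
individuals"; silent cancers undetected in both arms form a residual that is
identical across arms and cancels out of every incremental quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from lcscea.parameters import STAGES, Demography, ParameterSet
from lcscea.synthetic_data import LifeTable, ScreeningOutcomeModel, make_life_table

ARMS = ("screening", "no_screening")


def _annual_survival(q: float, bg_mult: float) -> float:
    """One-year survival with the background hazard scaled by bg_mult."""
    if q >= 1.0:
        return 0.0
    return math.exp(bg_mult * math.log1p(-q))


def eligible_population(d: Demography):
    """(aged 50-74, screening-eligible) head counts from demography."""
    aged = round(d.total_population * d.frac_aged_50_74)
    eligible = round(aged * d.smoking_rate)
    return int(aged), int(eligible)


def participants(eligible: float, uptake: float) -> int:
    """Number of individuals ever joining the program (floor rounding)."""
    if not (0.0 <= uptake <= 1.0):
        raise ValueError("uptake must lie in [0, 1]")
    return int(math.floor(eligible * uptake))


def allocate_clinical_stages(n: float, dist) -> Dict[str, int]:
    """Apply a clinical stage distribution to a diagnosis total.

    ``dist`` is either a mapping stage->fraction or a 4-sequence (I-IV).
    Returns nearest-integer counts; use ``n * dist`` directly where the
    unrounded mass is needed.
    """
    if not isinstance(dist, dict):
        dist = dict(zip(STAGES, dist))
    total = sum(dist[s] for s in STAGES)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"stage distribution sums to {total}, not 1")
    return {s: int(round(n * dist[s])) for s in STAGES}


def qalys_per_patient(delta_qaly: float, screen_arm_diagnoses: float) -> float:
    """Incremental QALYs per screening-arm diagnosis, to 2 decimals."""
    if screen_arm_diagnoses <= 0:
        raise ValueError("diagnoses must be positive")
    return round(delta_qaly / screen_arm_diagnoses, 2)


@dataclass
class DiagnosisLedger:
    """Diagnosis mass by arm, stage, pathway and calendar year, plus the
    per-round screening activity needed for program costing."""

    entry_age: float
    horizon_years: int
    aged_50_74: int
    eligible: int
    n_participants: int
    # pathway masses: stage -> {year -> mass}
    screen_detected: Dict[str, Dict[int, float]]
    clinical: Dict[str, Dict[str, Dict[int, float]]]  # arm -> stage -> year -> mass
    missed: Dict[int, float]  # no-screening arm only; year of cancer onset
    residual: Dict[int, float]  # identical in both arms; year of onset
    # per-round screening activity
    screens: np.ndarray
    false_positives: np.ndarray
    indeterminates: np.ndarray
    invitation_letters: int
    gp_consults: int
    # cancer-free mass at each year start (shared across arms)
    cancer_free_by_year: np.ndarray
    incident_by_year: Dict[int, float] = field(default_factory=dict)

    # -- aggregation helpers ------------------------------------------------
    def diagnoses_by_stage(self, arm: str) -> Dict[str, float]:
        out = {}
        for st in STAGES:
            mass = sum(self.clinical[arm][st].values())
            if arm == "screening":
                mass += sum(self.screen_detected[st].values())
            out[st] = mass
        return out

    def total_diagnoses(self, arm: str) -> float:
        return sum(self.diagnoses_by_stage(arm).values())

    def stage_shares(self, arm: str) -> Dict[str, float]:
        by_stage = self.diagnoses_by_stage(arm)
        total = sum(by_stage.values())
        return {s: (by_stage[s] / total if total else 0.0) for s in STAGES}

    def total_incident(self) -> float:
        return sum(self.incident_by_year.values())

    def undiagnosed_mass(self, arm: str) -> float:
        mass = sum(self.residual.values())
        if arm == "no_screening":
            mass += sum(self.missed.values())
        return mass

    def conservation_error(self) -> float:
        """Max relative deviation of per-arm (diagnosed + never-diagnosed)
        mass from the total incident mass."""
        total = self.total_incident()
        if total == 0:
            return 0.0
        errs = [
            abs(self.total_diagnoses(arm) + self.undiagnosed_mass(arm) - total) / total
            for arm in ARMS
        ]
        return max(errs)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: (arm, stage, detection_mode, year, count)."""
        rows = []
        for st in STAGES:
            for year, mass in sorted(self.screen_detected[st].items()):
                rows.append(("screening", st, "screen", year, mass))
            for arm in ARMS:
                for year, mass in sorted(self.clinical[arm][st].items()):
                    rows.append((arm, st, "clinical", year, mass))
        for year, mass in sorted(self.missed.items()):
            rows.append(("no_screening", "missed", "never", year, mass))
        for arm in ARMS:
            for year, mass in sorted(self.residual.items()):
                rows.append((arm, "residual", "never", year, mass))
        return pd.DataFrame(
            rows, columns=["arm", "stage", "detection_mode", "year", "count"]
        )


def simulate_arms(
    p: ParameterSet,
    som: ScreeningOutcomeModel,
    lt: Optional[LifeTable] = None,
) -> DiagnosisLedger:
    """Run the decision tree for both arms and return the diagnosis ledger."""
    lt = lt or make_life_table()
    s = p.settings
    aged, eligible = eligible_population(p.demography)
    n_part = participants(eligible, s.uptake)
    n_nonpart = eligible - n_part

    n_rounds = s.n_rounds
    delay = int(som.clinical_delay_years)
    horizon_years = int(math.ceil(s.horizon))
    inc = p.epidemiology.annual_incidence_eligible
    clin_dist = p.epidemiology.clinical_stage_distribution
    ad = s.adherence * som.detection_prob_per_round
    f = som.clinical_detection_fraction
    entry_age = p.demography.mean_entry_age
    bg_mult = p.background_mortality_multiplier

    screen_detected: Dict[str, Dict[int, float]] = {st: {} for st in STAGES}
    clinical = {arm: {st: {} for st in STAGES} for arm in ARMS}
    missed: Dict[int, float] = {}
    residual: Dict[int, float] = {}
    incident: Dict[int, float] = {}
    pool = np.zeros(n_rounds)  # undiagnosed pre-clinical mass present at each round
    screen_mass_total = 0.0

    def add(table, stage, year, mass):
        if mass > 0:
            table[stage][year] = table[stage].get(year, 0.0) + mass

    def stage_split(table, year, mass):
        for st in STAGES:
            add(table, st, year, mass * clin_dist[st])

    def process_cohort(y: int, m: float, is_participant: bool):
        """One incident cohort: onset year y (may predate the program)."""
        nonlocal screen_mass_total
        t_clin = y + delay
        a_mass = f * m  # clinically destined
        b_mass = m - a_mass  # silent unless screened
        if not is_participant:
            for arm in ARMS:
                stage_split(clinical[arm], t_clin, a_mass)
            residual[y] = residual.get(y, 0.0) + b_mass
            return
        r_start = max(y + 1, 0)
        # clinically destined: screenable until presentation (screen first at
        # the coincident round)
        rem = a_mass
        for r in range(r_start, min(t_clin, n_rounds - 1) + 1):
            pool[r] += rem
            det = rem * ad
            if det > 0:
                for st, share in zip(STAGES, som.screen_stage_distribution):
                    add(screen_detected, st, r, det * share)
                screen_mass_total += det
            rem -= det
        stage_split(clinical["screening"], t_clin, rem)
        stage_split(clinical["no_screening"], t_clin, a_mass)
        # silent: screenable through the whole window
        rem = b_mass
        detected = 0.0
        for r in range(r_start, n_rounds):
            pool[r] += rem
            det = rem * ad
            if det > 0:
                for st, share in zip(STAGES, som.screen_stage_distribution):
                    add(screen_detected, st, r, det * share)
                screen_mass_total += det
                detected += det
            rem -= det
        missed[y] = missed.get(y, 0.0) + detected
        residual[y] = residual.get(y, 0.0) + rem

    # shared incident process; pre-program onsets fill the prevalent pool
    cf_part = float(n_part)
    cf_non = float(n_nonpart)
    # the tree runs through all rounds even when the accumulation horizon is
    # shorter; economics truncates accrual, not transitions
    span = max(horizon_years, n_rounds)
    cf_by_year = np.zeros(span + 1)
    for y in range(-delay, n_rounds):
        if y >= 0:
            cf_by_year[y] = cf_part + cf_non
        m_p = cf_part * inc
        m_n = cf_non * inc
        incident[y] = m_p + m_n
        cf_part -= m_p
        cf_non -= m_n
        process_cohort(y, m_p, is_participant=True)
        process_cohort(y, m_n, is_participant=False)
        if y >= 0:
            surv = _annual_survival(lt.q(entry_age + y), bg_mult)
            cf_part *= surv
            cf_non *= surv
    for y in range(n_rounds, span + 1):
        cf_by_year[y] = cf_part + cf_non
        surv = _annual_survival(lt.q(entry_age + y), bg_mult)
        cf_part *= surv
        cf_non *= surv

    part_share = n_part / eligible if eligible else 0.0
    cf_part_by_round = cf_by_year[:n_rounds] * part_share
    screens = s.adherence * (cf_part_by_round + pool)
    fp = screens * som.false_positive_rate
    ind = screens * som.indeterminate_rate

    return DiagnosisLedger(
        entry_age=entry_age,
        horizon_years=horizon_years,
        aged_50_74=aged,
        eligible=eligible,
        n_participants=n_part,
        screen_detected=screen_detected,
        clinical=clinical,
        missed=missed,
        residual=residual,
        screens=screens,
        false_positives=fp,
        indeterminates=ind,
        # no participants means no program: nothing is mailed (keeps uptake=0
        # an exact null intervention)
        invitation_letters=aged if n_part > 0 else 0,
        gp_consults=n_part,
        cancer_free_by_year=cf_by_year,
        incident_by_year=incident,
    )
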