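"""Synthetic stand-ins for inputs that only exist outside the printed tables.

Provides a calibratable screening-outcome model (per-round detection,
screen-detected stage distribution, false-positive/indeterminate rates,
clinical-detection behaviour), a Gompertz-Makeham life table, age-specific
population utilities, and noisy survival anchors for fit-recovery tests.
All defaults are calibration artifacts, not trial estimates.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from lcscea.survival import FittedCurve, survival_at

#: Arm-level calibration targets: screening-arm stage shares for stages I-IV
#: and the screening/no-screening diagnosis ratio.
ARM_SHARE_TARGETS = (0.51, 0.07, 0.20, 0.22)
DIAGNOSIS_RATIO_TARGET = 1.501


@dataclass(frozen=True)
class ScreeningOutcomeModel:
    """Per-round screen performance and clinical-detection behaviour."""

    screen_stage_distribution: Tuple[float, float, float, float]
    detection_prob_per_round: float
    false_positive_rate: float
    indeterminate_rate: float
    clinical_detection_fraction: float
    clinical_delay_years: int = 2

    def __post_init__(self):
        if abs(sum(self.screen_stage_distribution) - 1.0) > 1e-9:
            raise ValueError("screen_stage_distribution must sum to 1")
        for name in (
            "detection_prob_per_round",
            "false_positive_rate",
            "indeterminate_rate",
            "clinical_detection_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


# Frozen output of calibrate_screening_outcomes() against the arm-level
# targets above (see scripts/ and the test suite); regenerate with
# calibrate_screening_outcomes(table1_fixture()).
_DEFAULT_SOM = ScreeningOutcomeModel(
    screen_stage_distribution=(0.695164, 0.065731, 0.158912, 0.080193),
    detection_prob_per_round=0.810121,
    false_positive_rate=0.01,
    indeterminate_rate=0.02,
    clinical_detection_fraction=0.49097,
    clinical_delay_years=8,
)


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities q(age) up to max_age, where q(max_age) = 1."""

    qx: Dict[int, float] = field(repr=False)
    max_age: int = 108

    def q(self, age: float) -> float:
        a = min(int(math.floor(age)), self.max_age)
        return self.qx.get(a, self.qx[min(self.qx)] if a < min(self.qx) else 1.0)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["age", "q"])
            for age in sorted(self.qx):
                w.writerow([age, repr(self.qx[age])])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        qx: Dict[int, float] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                qx[int(row["age"])] = float(row["q"])
        return cls(qx=qx, max_age=max(qx))


def make_life_table(
    a: float = 5e-5, b: float = 0.095, c: float = 5e-4, max_age: int = 108
) -> LifeTable:
    """Gompertz-Makeham life table: q(age) = 1 - exp(-(c + a*exp(b*age)))."""
    if a < 0 or c < 0 or max_age < 1:
        raise ValueError("life-table parameters must be non-negative, max_age >= 1")
    qx = {}
    for age in range(0, max_age + 1):
        q = -math.expm1(-(c + a * math.exp(b * age)))
        qx[age] = min(max(q, 0.0), 1.0)
    qx[max_age] = 1.0
    return LifeTable(qx=qx, max_age=max_age)


def make_population_utilities(u50: float = 0.89, slope: float = 0.003) -> Dict[int, float]:
    """Age-specific population utilities: linear decrement from age 50."""
    if not (0.0 < u50 <= 1.0):
        raise ValueError("u50 must lie in (0, 1]")
    if slope < 0:
        raise ValueError("slope must be >= 0")
    return {age: max(0.0, u50 - slope * (age - 50)) for age in range(50, 111)}


def make_km_anchors(
    curve: FittedCurve,
    times: Sequence[float],
    n_at_risk: int,
    seed: Optional[int] = None,
) -> list:
    """Binomially perturbed survival anchors around a true curve."""
    times = list(times)
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    if n_at_risk <= 0:
        raise ValueError("n_at_risk must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for t in times:
        s = survival_at(curve, t)
        obs = rng.binomial(n_at_risk, s) / n_at_risk
        out.append((t, float(obs)))
    return out


# ---------------------------------------------------------------------------
# screening-outcome model construction and calibration


def make_screening_outcomes(
    seed: Optional[int] = None,
    calibration: Optional[Sequence[float]] = None,
) -> ScreeningOutcomeModel:
    """Return a screening-outcome model.

    With no arguments, the frozen calibrated default is returned (end-to-end
    runs with the base-case fixture reproduce the arm-level stage-share and
    diagnosis-ratio targets).  ``calibration`` re-solves the screen-detected
    stage distribution against the given target arm shares.  ``seed`` jitters
    the default rates deterministically, for property tests.
    """
    som = _DEFAULT_SOM
    if calibration is not None:
        shares = tuple(float(x) for x in calibration)
        if abs(sum(shares) - 1.0) > 1e-9:
            raise ValueError("calibration shares must sum to 1")
        ssd = _invert_stage_distribution(shares, som)
        som = replace(som, screen_stage_distribution=ssd)
    if seed is not None:
        rng = np.random.default_rng(seed)
        ssd = np.array(som.screen_stage_distribution) * rng.uniform(0.9, 1.1, 4)
        ssd = ssd / ssd.sum()
        som = replace(
            som,
            screen_stage_distribution=tuple(float(x) for x in ssd),
            detection_prob_per_round=float(
                np.clip(som.detection_prob_per_round * rng.uniform(0.9, 1.1), 0, 1)
            ),
            clinical_detection_fraction=float(
                np.clip(som.clinical_detection_fraction * rng.uniform(0.9, 1.1), 0, 1)
            ),
        )
    return som


def _arm_composition(som: ScreeningOutcomeModel):
    """Screen-detected weight and clinical weight of screening-arm diagnoses
    under the base-case fixture (lazy import avoids a module cycle)."""
    from lcscea.cohort_tree import simulate_arms
    from lcscea.parameters import STAGES, table1_fixture

    p = table1_fixture()
    ledger = simulate_arms(p, som)
    screen = sum(sum(cohort.values()) for cohort in ledger.screen_detected.values())
    clinical = sum(
        sum(ledger.clinical["screening"][st].values()) for st in STAGES
    )
    return screen, clinical, p


def _invert_stage_distribution(targets, som) -> Tuple[float, ...]:
    """Solve the screen-detected stage distribution so the mixed screening-arm
    shares match ``targets``; clipped to the simplex."""
    screen_w, clin_w, p = _arm_composition(som)
    total = screen_w + clin_w
    if screen_w <= 0:
        return tuple(targets)
    clin = [p.epidemiology.clinical_stage_distribution[s] for s in ("I", "II", "III", "IV")]
    raw = [
        (targets[i] * total - clin_w * clin[i]) / screen_w for i in range(4)
    ]
    clipped = np.clip(raw, 0.0, None)
    if clipped.sum() == 0:
        return (0.25, 0.25, 0.25, 0.25)
    out = clipped / clipped.sum()
    return tuple(float(x) for x in out)


def calibrate_screening_outcomes(
    p=None,
    targets: Sequence[float] = ARM_SHARE_TARGETS,
    ratio_target: float = DIAGNOSIS_RATIO_TARGET,
) -> ScreeningOutcomeModel:
    """Least-squares calibration of the free screen-performance parameters.

    Solves (stage distribution x3 free, clinical detection fraction, per-round
    detection probability) so that a full decision-tree run with the base-case
    fixture reproduces the target screening-arm stage shares and the
    screening/no-screening diagnosis-ratio target.
    """
    from scipy.optimize import least_squares

    from lcscea.cohort_tree import simulate_arms
    from lcscea.parameters import STAGES, table1_fixture

    p = p or table1_fixture()

    def unpack(x):
        logits = np.concatenate([x[:3], [0.0]])
        ssd = np.exp(logits - logits.max())
        ssd = ssd / ssd.sum()
        f = 1.0 / (1.0 + math.exp(-x[3]))
        d = 1.0 / (1.0 + math.exp(-x[4]))
        return ScreeningOutcomeModel(
            screen_stage_distribution=tuple(float(v) for v in ssd),
            detection_prob_per_round=d,
            false_positive_rate=_DEFAULT_SOM.false_positive_rate,
            indeterminate_rate=_DEFAULT_SOM.indeterminate_rate,
            clinical_detection_fraction=f,
            clinical_delay_years=_DEFAULT_SOM.clinical_delay_years,
        )

    def residuals(x):
        som = unpack(x)
        ledger = simulate_arms(p, som)
        shares = ledger.stage_shares("screening")
        ratio = ledger.total_diagnoses("screening") / ledger.total_diagnoses("no_screening")
        return np.array(
            [shares[s] - t for s, t in zip(STAGES, targets)]
            + [(ratio - ratio_target) / ratio_target]
        )

    x0 = np.array([1.2, -1.0, -0.5, 0.0, 2.0])
    sol = least_squares(residuals, x0, method="lm", max_nfev=4000)
    return unpack(sol.x)
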