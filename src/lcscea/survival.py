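"""Parametric survival curves from summary anchors and per-cycle transition matrices.

Curves are fitted on the log-cumulative-hazard scale, extrapolated over the
lifetime horizon, and converted into 3x3 per-cycle transition probabilities
(pre-progression, post-progression, dead) with additive background mortality
and a proportional cause-of-death split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic", "gompertz")

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "lognormal": 2,
    "loglogistic": 2,
    "gompertz": 2,
}

#: hazard cap applied where a life-table annual death probability reaches 1
HAZARD_CAP = 50.0


class NumericalConsistencyError(RuntimeError):
    """OS/DPFS ordering violated beyond the clipping tolerance."""


@dataclass(frozen=True)
class FittedCurve:
    """A parametric survival function S(t) for one stage and endpoint."""

    family: str
    params: Tuple[float, ...]
    endpoint: str = "OS"
    stage: str = ""

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown survival family {self.family!r}")
        if self.family == "gompertz" and self.params[1] <= 0:
            raise ValueError("gompertz slope must be positive (S must vanish at infinity)")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": list(self.params),
            "endpoint": self.endpoint,
            "stage": self.stage,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FittedCurve":
        return cls(
            family=data["family"],
            params=tuple(data["params"]),
            endpoint=data.get("endpoint", "OS"),
            stage=data.get("stage", ""),
        )


def survival_at(c: FittedCurve, t):
    """Evaluate S(t); accepts scalars or arrays, t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    f, p = c.family, c.params
    if f == "exponential":
        s = np.exp(-p[0] * t)
    elif f == "weibull":
        shape, scale = p
        s = np.exp(-((t / scale) ** shape))
    elif f == "lognormal":
        mu, sigma = p
        with np.errstate(divide="ignore"):
            s = np.where(t > 0, stats.norm.sf((np.log(np.maximum(t, 1e-300)) - mu) / sigma), 1.0)
    elif f == "loglogistic":
        alpha, beta = p
        s = 1.0 / (1.0 + (t / alpha) ** beta)
    else:  # gompertz
        a, b = p
        s = np.exp(-(a / b) * (np.expm1(b * t)))
    return float(s) if s.ndim == 0 else s


def cumulative_hazard(c: FittedCurve, t):
    s = survival_at(c, t)
    s = np.clip(s, 1e-300, 1.0)
    return -np.log(s)


def _log_ch(family: str, params, t):
    """log cumulative hazard per family, vectorized over t."""
    c = FittedCurve(family=family, params=tuple(params))
    return np.log(np.maximum(cumulative_hazard(c, t), 1e-300))


def fit_curve(
    anchors: Sequence[Tuple[float, float]],
    family: str = "auto",
    endpoint: str = "OS",
    stage: str = "",
) -> FittedCurve:
    """Fit a parametric curve to (time, survival) summary anchors.

    A single anchor identifies only the exponential family (closed form
    ``lambda = -ln(S)/t``).  With two or more anchors the fit is least
    squares on the log-cumulative-hazard scale; ``family="auto"`` picks the
    minimum-AIC family among those with at most ``len(anchors) - 1`` free
    parameters.
    """
    if len(anchors) < 1:
        raise ValueError("need at least one anchor")
    times = np.asarray([a[0] for a in anchors], dtype=float)
    surv = np.asarray([a[1] for a in anchors], dtype=float)
    if np.any(times <= 0):
        raise ValueError("anchor times must be positive")
    if np.any((surv <= 0) | (surv >= 1)):
        raise ValueError("anchor survival values must lie strictly in (0, 1)")

    if len(anchors) == 1:
        if family not in ("auto", "exponential"):
            raise ValueError("a single anchor identifies only the exponential family")
        lam = -math.log(surv[0]) / times[0]
        return FittedCurve("exponential", (lam,), endpoint, stage)

    log_h = np.log(-np.log(surv))
    log_t = np.log(times)

    def fit_one(fam: str) -> Tuple[FittedCurve, float]:
        if fam == "exponential":
            lam = math.exp(float(np.mean(log_h - log_t)))
            params: Tuple[float, ...] = (lam,)
        elif fam == "weibull":
            shape, intercept = np.polyfit(log_t, log_h, 1)
            shape = max(shape, 1e-8)
            scale = math.exp(-intercept / shape)
            params = (shape, scale)
        else:
            x0 = {
                "lognormal": np.array([np.mean(log_t), 1.0]),
                "loglogistic": np.array([math.exp(np.mean(log_t)), 1.0]),
                "gompertz": np.array([0.1, 0.1]),
            }[fam]

            def resid(x):
                if fam == "lognormal":
                    p = (x[0], abs(x[1]) + 1e-8)
                else:
                    p = (abs(x[0]) + 1e-12, abs(x[1]) + 1e-8)
                return _log_ch(fam, p, times) - log_h

            sol = optimize.least_squares(resid, x0, method="lm", max_nfev=2000)
            if fam == "lognormal":
                params = (float(sol.x[0]), abs(float(sol.x[1])) + 1e-8)
            else:
                params = (abs(float(sol.x[0])) + 1e-12, abs(float(sol.x[1])) + 1e-8)
        curve = FittedCurve(fam, params, endpoint, stage)
        rss = float(np.sum((_log_ch(fam, params, times) - log_h) ** 2))
        n, k = len(times), _N_PARAMS[fam]
        aic = n * math.log(max(rss, 1e-300) / n) + 2 * k
        return curve, aic

    if family != "auto":
        if family not in FAMILIES:
            raise ValueError(f"unknown survival family {family!r}")
        return fit_one(family)[0]

    candidates = [f for f in FAMILIES if _N_PARAMS[f] <= len(anchors) - 1]
    fits = [fit_one(f) for f in candidates]
    return min(fits, key=lambda fa: fa[1])[0]


def prob_to_cycle(p_annual: float, cycle: float) -> float:
    """Constant-hazard conversion of an annual probability to a cycle probability."""
    if not (0.0 <= p_annual <= 1.0):
        raise ValueError("p_annual must lie in [0, 1]")
    if cycle <= 0:
        raise ValueError("cycle must be positive")
    return 1.0 - (1.0 - p_annual) ** cycle


def life_table_hazard(lt, age: float) -> float:
    """Annual all-cause hazard at (floored) age; capped at HAZARD_CAP."""
    q = lt.q(age)
    if q >= 1.0:
        return HAZARD_CAP
    if q <= 0.0:
        return 0.0
    return min(-math.log1p(-q), HAZARD_CAP)


@dataclass(frozen=True)
class TransitionMatrix:
    """One-cycle 3x3 transition probabilities with a lung-cancer death split."""

    matrix: np.ndarray  # rows/cols: pre, post, dead
    lc_share_pre: float  # share of pre-state deaths attributed to lung cancer
    lc_share_post: float

    def __post_init__(self):
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if self.matrix[2, 0] != 0.0 or self.matrix[2, 1] != 0.0:
            raise ValueError("dead state must be absorbing")


def _interval_hazard(curve: Optional[FittedCurve], t: float, cycle: float) -> float:
    """Average hazard rate of a curve over [t, t + cycle]."""
    if curve is None:
        return 0.0
    h0 = cumulative_hazard(curve, t)
    h1 = cumulative_hazard(curve, t + cycle)
    return min(float(h1 - h0) / cycle, HAZARD_CAP)


def cycle_matrix(
    os_curve: FittedCurve,
    dpfs_curve: Optional[FittedCurve],
    lt,
    age: float,
    t: float,
    cycle: float,
    bg_mult: float = 1.0,
    post_os: Optional[FittedCurve] = None,
) -> TransitionMatrix:
    """Build the per-cycle transition matrix for one stratum at time t.

    Death hazards are additive: the disease hazard from the OS curve plus
    ``bg_mult`` times the background (life-table) hazard, with the
    cause-of-death split proportional to the two components.  Progression
    uses the DPFS excess hazard, clipped at zero; a negative excess beyond
    tolerance raises :class:`NumericalConsistencyError`.  Post-progression
    death follows ``post_os`` (defaults to the OS curve).
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    lam_d = _interval_hazard(os_curve, t, cycle)
    lam_b = bg_mult * (life_table_hazard(lt, age) if lt is not None else 0.0)

    if dpfs_curve is not None:
        h_os = float(cumulative_hazard(os_curve, t))
        h_dpfs = float(cumulative_hazard(dpfs_curve, t))
        if h_dpfs < h_os - 1e-9 and survival_at(os_curve, t) < survival_at(dpfs_curve, t) - 1e-9:
            raise NumericalConsistencyError(
                f"S_OS < S_DPFS for stage {os_curve.stage!r} at t={t}"
            )
        mu_e = max(0.0, _interval_hazard(dpfs_curve, t, cycle) - lam_d)
    else:
        mu_e = 0.0

    p_die_pre = -math.expm1(-(lam_d + lam_b) * cycle)
    p_prog = math.exp(-(lam_d + lam_b) * cycle) * (-math.expm1(-mu_e * cycle))
    p_stay = 1.0 - p_die_pre - p_prog

    lam_post = _interval_hazard(post_os or os_curve, t, cycle)
    p_die_post = -math.expm1(-(lam_post + lam_b) * cycle)

    def lc_share(disease, background):
        tot = disease + background
        return disease / tot if tot > 0 else 0.0

    m = np.array(
        [
            [p_stay, p_prog, p_die_pre],
            [0.0, 1.0 - p_die_post, p_die_post],
            [0.0, 0.0, 1.0],
        ]
    )
    return TransitionMatrix(m, lc_share(lam_d, lam_b), lc_share(lam_post, lam_b))


def fit_base_curves(p) -> Dict[str, Dict[str, Optional[FittedCurve]]]:
    """Fit OS and DPFS curves for every stage (plus the missed stratum) from
    the parameter set's summary anchors."""
    from lcscea.parameters import MISSED, STAGES

    curves: Dict[str, Dict[str, Optional[FittedCurve]]] = {}
    for st in STAGES:
        os_c = fit_curve([(5.0, p.survival.os_5yr[st])], "exponential", "OS", st)
        dpfs_c = fit_curve([(1.0, p.survival.dpfs_1yr[st])], "exponential", "DPFS", st)
        if st in ("III", "IV") and p.special_flags.late_stage_hazard_multiplier != 1.0:
            k = p.special_flags.late_stage_hazard_multiplier
            os_c = FittedCurve("exponential", (os_c.params[0] * k,), "OS", st)
        curves[st] = {"os": os_c, "dpfs": dpfs_c}
    proxy = p.survival.missed_behaves_as
    curves[MISSED] = {"os": curves[proxy]["os"], "dpfs": None}
    return curves
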