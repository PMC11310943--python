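"""One-way sensitivity analysis, probabilistic sensitivity analysis, CEAC
and the scenario runner."""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from lcscea.economics import EconomicResult, UndefinedICERError
from lcscea.parameters import (
    DistributionSpec,
    ParameterSet,
    Scenario,
    apply_scenario,
    get_path,
    set_path,
)
from lcscea.pipeline import run_model


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_low: float
    icer_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


@dataclass
class PsaSamples:
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    parameters: pd.DataFrame
    seed: Optional[int]

    @property
    def n_draws(self) -> int:
        return self.delta_cost.size


Runner = Callable[[ParameterSet], EconomicResult]


def default_osa_paths(p: ParameterSet) -> List[str]:
    """Parameters varied in the tornado: everything with a non-fixed distribution."""
    return [path for path, spec in p.distributions.items() if spec.kind != "fixed"]


def one_way(
    p: ParameterSet,
    param_paths: Sequence[str],
    delta: float = 0.2,
    runner: Runner = run_model,
) -> List[TornadoEntry]:
    """Rerun the full model at (1-delta) and (1+delta) times each parameter.

    Values that are probabilities (base value <= 1) are capped at 1 on the
    upside.  Entries come back sorted by span, largest first.
    """
    if not (0.0 < delta < 1.0):
        raise ValueError("delta must lie in (0, 1)")
    entries = []
    for path in param_paths:
        base = get_path(p, path)  # raises on bad path
        icers = []
        for factor in (1.0 - delta, 1.0 + delta):
            value = base * factor
            if base <= 1.0:
                value = min(value, 1.0)
            q = copy.deepcopy(p)
            set_path(q, path, value)
            res = runner(q)
            icers.append(res.delta_cost / res.delta_qaly if res.delta_qaly else np.nan)
        entries.append(TornadoEntry(path, icers[0], icers[1]))
    return sorted(entries, key=lambda e: e.span, reverse=True)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.parameter, e.icer_low, e.icer_high, e.span) for e in entries],
        columns=["parameter", "icer_low", "icer_high", "span"],
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


def _draw_value(spec: DistributionSpec, rng: np.random.Generator) -> float:
    if spec.kind == "fixed" or not spec.se:
        return spec.mean
    m, se = spec.mean, spec.se
    if spec.kind == "beta":
        if not (0.0 < m < 1.0):
            raise ValueError(f"beta mean {m} not in (0,1)")
        nu = m * (1.0 - m) / se**2 - 1.0
        if nu <= 0:
            raise ValueError(f"beta se {se} too large for mean {m}")
        return float(rng.beta(m * nu, (1.0 - m) * nu))
    if spec.kind == "gamma":
        shape = (m / se) ** 2
        scale = se**2 / m
        return float(rng.gamma(shape, scale))
    raise ValueError(f"cannot draw {spec.kind} marginally")


#: dirichlet concentration per unit mean share
DIRICHLET_SCALE = 100.0


def sample_psa(
    p: ParameterSet,
    n: int,
    seed: Optional[int] = None,
    runner: Runner = run_model,
) -> PsaSamples:
    """Joint parameter draws (beta/gamma moment-matched, dirichlet groups
    drawn together) with one full model evaluation per draw."""
    if n < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    groups: Dict[str, List[str]] = {}
    for path, spec in p.distributions.items():
        if spec.kind == "dirichlet_group":
            groups.setdefault(spec.group_id or path, []).append(path)

    dc = np.empty(n)
    dq = np.empty(n)
    records = []
    for i in range(n):
        q = copy.deepcopy(p)
        row: Dict[str, float] = {}
        for path, spec in p.distributions.items():
            if spec.kind in ("fixed", "dirichlet_group"):
                continue
            try:
                value = _draw_value(spec, rng)
            except ValueError as err:
                raise ValueError(f"PSA distribution for {path!r}: {err}") from err
            set_path(q, path, value)
            row[path] = value
        for gid, paths in groups.items():
            means = np.array([p.distributions[path].mean for path in paths])
            # se explicitly 0 on every member marks the group degenerate;
            # se=None means "use the default concentrations"
            if all(p.distributions[path].se == 0.0 for path in paths):
                draws = means
            else:
                draws = rng.dirichlet(means * DIRICHLET_SCALE)
            for path, value in zip(paths, draws):
                set_path(q, path, float(value))
                row[path] = float(value)
        res = runner(q)
        dc[i] = res.delta_cost
        dq[i] = res.delta_qaly
        records.append(row)
    return PsaSamples(dc, dq, pd.DataFrame.from_records(records), seed)


def probabilistic_icer(s: PsaSamples, method: str = "ratio_of_means") -> float:
    """Probabilistic ICER; ratio of means by default."""
    mean_dq = float(np.mean(s.delta_qaly))
    if mean_dq == 0:
        raise UndefinedICERError("mean incremental QALYs is zero")
    if method == "ratio_of_means":
        return float(np.mean(s.delta_cost)) / mean_dq
    if method == "mean_of_ratios":
        return float(np.mean(s.delta_cost / s.delta_qaly))
    raise ValueError(f"unknown method {method!r}")


def ceac(s: PsaSamples, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Probability the intervention is cost-effective at each WTP threshold."""
    grid = list(wtp_grid)
    if not grid:
        raise ValueError("wtp_grid must be nonempty")
    probs = [
        float(np.mean(wtp * s.delta_qaly - s.delta_cost > 0)) for wtp in grid
    ]
    return pd.DataFrame({"wtp": grid, "prob_cost_effective": probs})


def ce_plane_frame(s: PsaSamples) -> pd.DataFrame:
    return pd.DataFrame({"delta_cost": s.delta_cost, "delta_qaly": s.delta_qaly})


# ---------------------------------------------------------------------------
# scenarios


def run_scenarios(
    p: ParameterSet,
    scenarios: Sequence[Scenario],
    runner: Runner = run_model,
) -> pd.DataFrame:
    """One full pipeline run per scenario; output shaped like a scenario table."""
    rows = []
    for sc in scenarios:
        try:
            res = runner(apply_scenario(p, sc))
        except Exception as err:
            raise RuntimeError(f"scenario {sc.name!r} failed: {err}") from err
        rows.append(
            {
                "scenario": sc.name,
                "screening_total_cost": res.arms["screening"].total_cost,
                "screening_total_qalys": res.arms["screening"].qalys,
                "no_screening_total_cost": res.arms["no_screening"].total_cost,
                "no_screening_total_qalys": res.arms["no_screening"].qalys,
                "delta_cost": res.delta_cost,
                "delta_qalys": res.delta_qaly,
                "icer": res.icer_qaly,
            }
        )
    return pd.DataFrame(rows)


def standard_scenarios() -> List[Scenario]:
    """The shipped scenario set (horizons, discounting, rounds, uptake,
    adherence, smoking rate, CT cost, cessation, disutility, utilities,
    background mortality)."""
    from lcscea.parameters import SpecialFlags

    out = [Scenario(name="base case")]
    for h in (10, 20, 30):
        out.append(Scenario(name=f"time horizon {h}y", overrides={"settings.horizon": float(h)}))
    for r in (0.0, 0.03, 0.10):
        out.append(
            Scenario(
                name=f"discount rates {r:.0%}",
                overrides={
                    "settings.discount_rate_costs": r,
                    "settings.discount_rate_health": r,
                },
            )
        )
    for n in (3, 5, 10, 15):
        out.append(Scenario(name=f"{n} screening rounds", overrides={"settings.n_rounds": n}))
    for u in (0.154, 0.168, 0.41):
        out.append(Scenario(name=f"uptake {u:.1%}", overrides={"settings.uptake": u}))
    for a in (0.3, 0.5, 0.7):
        out.append(Scenario(name=f"adherence {a:.0%}", overrides={"settings.adherence": a}))
    for sm in (0.15, 0.10, 0.05):
        out.append(Scenario(name=f"smoking rate {sm:.0%}", overrides={"demography.smoking_rate": sm}))
    for ct in (82.0, 103.0, 175.0):
        out.append(Scenario(name=f"CT scan EUR {ct:.0f}", overrides={"costs.ct_scan": ct}))
    for c in (300.0, 400.0):
        out.append(
            Scenario(
                name=f"smoking cessation EUR {c:.0f}",
                special_flags=SpecialFlags(smoking_cessation_cost=c),
            )
        )
    for du in (0.015, 0.03, 0.05):
        out.append(
            Scenario(
                name=f"FP/indeterminate disutility {du}",
                special_flags=SpecialFlags(fp_disutility=du),
            )
        )
    for up in (0.1, 0.2, 0.5, 1.0):
        out.append(
            Scenario(
                name=f"immunotherapy uptake +{up:.0%}",
                special_flags=SpecialFlags(immunotherapy_uplift=up),
            )
        )
    out.append(
        Scenario(
            name="stage I utility +20%",
            overrides={
                "utilities.pre_progression.I": 0.936,
            },
        )
    )
    out.append(
        Scenario(
            name="background mortality +100%",
            overrides={"background_mortality_multiplier": 2.0},
        )
    )
    return out
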