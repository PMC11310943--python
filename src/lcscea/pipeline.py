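"""End-to-end orchestration: decision tree -> Markov engine -> economics."""

from __future__ import annotations

from typing import Optional, Tuple

from lcscea.cohort_tree import DiagnosisLedger, simulate_arms
from lcscea.economics import EconomicResult, evaluate
from lcscea.parameters import ParameterSet
from lcscea.survival import fit_base_curves
from lcscea.synthetic_data import (
    LifeTable,
    ScreeningOutcomeModel,
    make_life_table,
    make_screening_outcomes,
)


def run_model(
    p: ParameterSet,
    som: Optional[ScreeningOutcomeModel] = None,
    lt: Optional[LifeTable] = None,
) -> EconomicResult:
    """Deterministic full-model run for one parameter set."""
    return run_model_with_ledger(p, som, lt)[0]


def run_model_with_ledger(
    p: ParameterSet,
    som: Optional[ScreeningOutcomeModel] = None,
    lt: Optional[LifeTable] = None,
) -> Tuple[EconomicResult, DiagnosisLedger]:
    if som is None:
        if p.screening_outcomes:
            cfg = dict(p.screening_outcomes)
            cfg["screen_stage_distribution"] = tuple(cfg["screen_stage_distribution"])
            som = ScreeningOutcomeModel(**cfg)
        else:
            som = make_screening_outcomes()
    lt = lt or make_life_table()
    ledger = simulate_arms(p, som, lt)
    curves = fit_base_curves(p)
    result = evaluate(ledger, curves, lt, p)
    return result, ledger
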