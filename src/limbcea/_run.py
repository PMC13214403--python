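"""Internal: run one strategy end to end (matrices → trace → valuation)."""

from __future__ import annotations

import numpy as np

from .engine import CohortTrace, run_trace
from .lifetables import LifeTable, MortalityAdjustment
from .parameters import ModelParameters
from .transitions import NO_TREATMENT_STATES, SURGERY_STATES, matrix_sequence
from .valuation import INTERVENTION, REFERENCE, accumulate, assign_state_values

STRATEGIES = (REFERENCE, INTERVENTION)


def initial_occupancy(strategy: str) -> np.ndarray:
    """The cohort starts wholly in NormalLife (no treatment) or LLL (surgery)."""
    if strategy == REFERENCE:
        v = np.zeros(len(NO_TREATMENT_STATES))
    elif strategy == INTERVENTION:
        v = np.zeros(len(SURGERY_STATES))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    v[0] = 1.0
    return v


def strategy_states(strategy: str) -> tuple:
    return NO_TREATMENT_STATES if strategy == REFERENCE else SURGERY_STATES


def run_strategy(
    params: ModelParameters,
    life: LifeTable,
    adj: MortalityAdjustment,
    strategy: str,
) -> tuple[CohortTrace, float, float]:
    """Trace one strategy and return (trace, discounted QALYs, discounted cost)."""
    matrices = matrix_sequence(strategy, params, life, adj)
    trace = run_trace(
        initial_occupancy(strategy),
        matrices,
        strategy_states(strategy),
        strategy=strategy,
        start_age=params.start_age,
    )
    qalys, costs = accumulate(trace, assign_state_values(params, strategy), params)
    return trace, qalys, costs
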