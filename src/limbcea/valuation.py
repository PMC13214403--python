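"""Attach utilities and costs to a cohort trace, discount, and compare
strategies on QALYs, costs, ICER and net monetary benefit.

Rewards follow the occupancy convention of :mod:`limbcea.engine`: the
occupancy lived during cycle ``t`` earns one year of that state's utility
and incurs that state's cost, both discounted by ``(1 + r)**(-t)``. The
terminal occupancy row (after the last transition) earns nothing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .engine import CohortTrace
from .parameters import ModelParameters
from .transitions import NO_TREATMENT_STATES, SURGERY_STATES

__all__ = [
    "StateValues",
    "EconResult",
    "assign_state_values",
    "discount_factor",
    "accumulate",
    "compare",
    "icer",
]

REFERENCE = "no_treatment"
INTERVENTION = "surgery"


@dataclass(frozen=True)
class StateValues:
    """Per-state utility (per year lived) and cost (per year occupied)."""

    states: tuple
    utilities: np.ndarray
    costs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "utilities", np.asarray(self.utilities, dtype=float))
        object.__setattr__(self, "costs", np.asarray(self.costs, dtype=float))
        if not (len(self.states) == len(self.utilities) == len(self.costs)):
            raise ValueError("states, utilities and costs must have equal length")


def assign_state_values(params: ModelParameters, strategy: str) -> StateValues:
    """Build the per-state utility and cost vectors for one strategy.

    Surgery-year utilities are the relevant disutility multiplier applied
    to the pathway's lifelong utility (``multiplier_base="pathway"``, the
    default) or to the untreated utility (``"baseline"``). Death carries
    zero utility and cost; lifelong normal-life states carry no incremental
    cost (shared costs cancel between the strategies).
    """
    if strategy == REFERENCE:
        u = {"NormalLife": params.u_base, "Death": 0.0}
        c = {"NormalLife": 0.0, "Death": 0.0}
        states = NO_TREATMENT_STATES
    elif strategy == INTERVENTION:
        if params.multiplier_base == "pathway":
            base_ll, base_ul = params.u_lll, params.u_full
        else:
            base_ll = base_ul = params.u_base
        u = {
            "LLL": params.m_lll * base_ll,
            "LLComp": params.m_llc * base_ll,
            "ULL": params.m_ull * base_ul,
            "ULComp": params.m_ulc * base_ul,
            "NormalLifeLLLOnly": params.u_lll,
            "NormalLifeFull": params.u_full,
            "Death": 0.0,
        }
        c = {
            "LLL": params.c_lll,
            "LLComp": params.c_comp,
            "ULL": params.c_ull,
            "ULComp": params.c_comp,
            "NormalLifeLLLOnly": 0.0,
            "NormalLifeFull": 0.0,
            "Death": 0.0,
        }
        states = SURGERY_STATES
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return StateValues(
        states=states,
        utilities=np.array([u[s] for s in states]),
        costs=np.array([c[s] for s in states]),
    )


def discount_factor(rate: float, cycle) -> np.ndarray | float:
    """``(1 + rate) ** (-cycle)``; cycle 0 is undiscounted."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    return (1.0 + rate) ** (-np.asarray(cycle, dtype=float))


def accumulate(
    trace: CohortTrace, values: StateValues, params: ModelParameters
) -> tuple[float, float]:
    """Discounted (QALYs, costs) of one strategy's trace.

    Sums over the cycles lived (rows ``0 .. n_cycles - 1``); QALYs discount
    at ``r_health``, costs at ``r_cost``.
    """
    if trace.states != values.states:
        raise ValueError(
            f"trace states {trace.states} do not match value states {values.states}"
        )
    lived = trace.occupancy[:-1]
    t = np.arange(lived.shape[0])
    qalys = float(np.sum(discount_factor(params.r_health, t) * (lived @ values.utilities)))
    costs = float(np.sum(discount_factor(params.r_cost, t) * (lived @ values.costs)))
    return qalys, costs


def icer(delta_cost: float, delta_qaly: float) -> float:
    """Incremental cost-effectiveness ratio ΔC/ΔE; NaN when ΔE == 0."""
    if delta_qaly == 0:
        return math.nan
    return delta_cost / delta_qaly


@dataclass(frozen=True)
class EconResult:
    """Per-strategy discounted totals and the pairwise comparison."""

    qalys: dict
    costs: dict
    wtp: float

    @property
    def delta_qaly(self) -> float:
        return self.qalys[INTERVENTION] - self.qalys[REFERENCE]

    @property
    def delta_cost(self) -> float:
        return self.costs[INTERVENTION] - self.costs[REFERENCE]

    @property
    def icer(self) -> float:
        return icer(self.delta_cost, self.delta_qaly)

    @property
    def dominance(self) -> str:
        """'intervention' / 'reference' if one strategy dominates, else ''."""
        if self.delta_qaly > 0 and self.delta_cost <= 0:
            return "intervention"
        if self.delta_qaly < 0 and self.delta_cost >= 0:
            return "reference"
        return ""

    def nmb(self, wtp: float | None = None) -> dict:
        """Net monetary benefit λ·QALYs − cost per strategy."""
        lam = self.wtp if wtp is None else wtp
        return {s: lam * self.qalys[s] - self.costs[s] for s in self.qalys}

    def to_dict(self) -> dict:
        return {
            "qalys": dict(self.qalys),
            "costs": dict(self.costs),
            "delta_qaly": self.delta_qaly,
            "delta_cost": self.delta_cost,
            "icer": self.icer,
            "icer_display": None if math.isnan(self.icer) else round(self.icer),
            "wtp": self.wtp,
            "nmb": self.nmb(),
            "dominance": self.dominance,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compare(qalys: dict, costs: dict, wtp: float) -> EconResult:
    """Pairwise comparison of the two strategies (reference: no treatment)."""
    expected = {REFERENCE, INTERVENTION}
    if set(qalys) != expected or set(costs) != expected:
        raise ValueError(f"expected exactly the strategies {sorted(expected)}")
    return EconResult(qalys=dict(qalys), costs=dict(costs), wtp=wtp)
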