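"""Budget impact: scale the per-patient incremental cost stream up to a
national program with one incident cohort per year over a fixed horizon.

Each year a new cohort of ``patients_per_year`` enters and generates the
surgery strategy's expected cost stream (which is exhausted within the
4-cycle surgical window). The no-treatment arm contributes zero incremental
spend. Yearly program spend is the sum over entry cohorts of their
stream at the appropriate lag; costs beyond the horizon are truncated.
Spend is discounted to program start by default (``discounting =
"program_start"``); ``"none"`` gives the undiscounted arithmetic total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._run import run_strategy
from .lifetables import LifeTable, MortalityAdjustment
from .parameters import ModelParameters
from .valuation import INTERVENTION, assign_state_values

__all__ = ["BudgetScenario", "BudgetResult", "per_patient_cost_stream", "run_budget"]


@dataclass(frozen=True)
class BudgetScenario:
    horizon_years: int = 15
    patients_per_year: float = 15
    discount_rate: float = 0.03
    discounting: str = "program_start"
    uptake_label: str = "full"

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ValueError(f"horizon_years must be >= 1, got {self.horizon_years}")
        if self.patients_per_year < 0:
            raise ValueError(f"patients_per_year must be >= 0, got {self.patients_per_year}")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError(f"discount_rate must be in [0, 1), got {self.discount_rate}")
        if self.discounting not in ("program_start", "none"):
            raise ValueError(
                f"discounting must be 'program_start' or 'none', got {self.discounting!r}"
            )


@dataclass(frozen=True)
class BudgetResult:
    """Per-year incremental program spend (€) and its cumulative total."""

    annual_spend: np.ndarray
    scenario: BudgetScenario

    @property
    def cumulative(self) -> float:
        return float(self.annual_spend.sum())

    def to_frame(self) -> pd.DataFrame:
        years = np.arange(1, len(self.annual_spend) + 1)
        return pd.DataFrame(
            {
                "year": years,
                "annual_spend": self.annual_spend,
                "cumulative_spend": np.cumsum(self.annual_spend),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def per_patient_cost_stream(
    params: ModelParameters,
    life: LifeTable,
    adj: MortalityAdjustment | None = None,
) -> np.ndarray:
    """Expected *undiscounted* incremental cost per year since a patient's
    entry (length ``n_cycles``; zero outside the surgical window).

    Its discounted sum at ``r_cost`` equals the valuation module's
    per-patient discounted incremental cost.
    """
    if adj is None:
        adj = MortalityAdjustment(surgical_mortality=params.surg_dp)
    trace, _, _ = run_strategy(params, life, adj, INTERVENTION)
    values = assign_state_values(params, INTERVENTION)
    return trace.occupancy[:-1] @ values.costs


def run_budget(scenario: BudgetScenario, stream: np.ndarray) -> BudgetResult:
    """Aggregate the per-patient stream over yearly incident cohorts.

    Program year ``y`` (0-based) spend is
    ``patients_per_year * sum_{e<=y} stream[y-e]``, discounted to program
    start when the scenario says so; the horizon truncates later costs.
    """
    stream = np.asarray(stream, dtype=float)
    H = scenario.horizon_years
    annual = np.zeros(H)
    for y in range(H):
        # cohorts entered at years 0..y contribute stream[y - e], i.e. stream[0..y]
        annual[y] = scenario.patients_per_year * float(stream[: y + 1].sum())
        if scenario.discounting == "program_start":
            annual[y] *= (1.0 + scenario.discount_rate) ** (-y)
    return BudgetResult(annual_spend=annual, scenario=scenario)
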