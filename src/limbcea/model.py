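"""Model and results objects tying the pipeline together.

:class:`MarkovCEA` holds the structural inputs (parameters, life table,
mortality adjustment). ``fit()`` runs the deterministic cohort model for
both strategies and returns :class:`CEAResults`; ``fit_psa()`` runs the
probabilistic sensitivity analysis and returns :class:`PSAResults`, from
which acceptability curves, the frontier and EVPI are computed;
``budget_impact()`` scales the per-patient cost stream to a national
program.

Example
-------
>>> from limbcea import MarkovCEA
>>> model = MarkovCEA()                    # base case, synthetic life table
>>> res = model.fit()
>>> print(res.summary())                   # doctest: +SKIP
>>> psa = model.fit_psa(n_iter=1000, seed=7)
>>> curves = psa.voi_curves()
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._run import STRATEGIES, run_strategy
from .budget import BudgetResult, BudgetScenario, per_patient_cost_stream, run_budget
from .distributions import default_specs
from .engine import CohortTrace
from .lifetables import LifeTable, MortalityAdjustment, gompertz_makeham_table
from .parameters import ModelParameters
from .psa import PSAResult, psa_summary, run_psa
from .valuation import EconResult, compare
from .voi import ceac, ceaf, evpi, make_wtp_grid, voi_curves

__all__ = ["MarkovCEA", "CEAResults", "PSAResults"]


class MarkovCEA:
    """Two-strategy Markov cohort cost-utility model.

    Parameters
    ----------
    params : ModelParameters, optional
        Base-case parameters (defaults to the published base case).
    life_table : LifeTable, optional
        General-population annual mortality; defaults to the synthetic
        Gompertz–Makeham table.
    adjustment : MortalityAdjustment, optional
        Age shift and surgical mortality; defaults to a 10-year shift with
        the parameter set's surgical mortality.
    """

    def __init__(
        self,
        params: ModelParameters | None = None,
        life_table: LifeTable | None = None,
        adjustment: MortalityAdjustment | None = None,
    ) -> None:
        self.params = params if params is not None else ModelParameters()
        self.life_table = life_table if life_table is not None else gompertz_makeham_table()
        self.adjustment = (
            adjustment
            if adjustment is not None
            else MortalityAdjustment(surgical_mortality=self.params.surg_dp)
        )

    @classmethod
    def from_config(cls, config) -> "MarkovCEA":
        """Build from a validated :class:`limbcea.config.RunConfig`."""
        from .config import build_model  # local import to avoid a cycle

        return build_model(config)

    def fit(self) -> "CEAResults":
        """Run the deterministic base case for both strategies."""
        traces, qalys, costs = {}, {}, {}
        for strategy in STRATEGIES:
            tr, q, c = run_strategy(self.params, self.life_table, self.adjustment, strategy)
            traces[strategy] = tr
            qalys[strategy] = q
            costs[strategy] = c
        econ = compare(qalys, costs, self.params.wtp)
        return CEAResults(model=self, traces=traces, econ=econ)

    def fit_psa(
        self, n_iter: int = 1000, seed: int | None = None, specs: dict | None = None
    ) -> "PSAResults":
        """Run the probabilistic sensitivity analysis."""
        if specs is None:
            specs = default_specs(self.params)
        raw = run_psa(
            self.params, self.life_table, n_iter=n_iter, seed=seed, specs=specs,
            adj=self.adjustment,
        )
        return PSAResults(model=self, raw=raw, specs=specs)

    def budget_impact(self, scenario: BudgetScenario | None = None) -> BudgetResult:
        """Budget impact of adopting the surgical program nationally."""
        if scenario is None:
            scenario = BudgetScenario(
                patients_per_year=self.params.incident_cases_per_year,
                discount_rate=self.params.r_cost,
            )
        stream = per_patient_cost_stream(self.params, self.life_table, self.adjustment)
        return run_budget(scenario, stream)


@dataclass(frozen=True)
class CEAResults:
    """Deterministic base-case results: traces, totals and the comparison."""

    model: MarkovCEA
    traces: dict
    econ: EconResult

    @property
    def qalys(self) -> dict:
        return self.econ.qalys

    @property
    def costs(self) -> dict:
        return self.econ.costs

    @property
    def delta_qaly(self) -> float:
        return self.econ.delta_qaly

    @property
    def delta_cost(self) -> float:
        return self.econ.delta_cost

    @property
    def icer(self) -> float:
        return self.econ.icer

    def nmb(self, wtp: float | None = None) -> dict:
        return self.econ.nmb(wtp)

    def to_dict(self) -> dict:
        return self.econ.to_dict()

    def summary(self) -> str:
        """Aligned-text comparison table (costs in €, ICER rounded to the euro)."""
        e = self.econ
        df = pd.DataFrame(
            {
                "QALYs": [e.qalys[s] for s in STRATEGIES],
                "Cost (EUR)": [e.costs[s] for s in STRATEGIES],
                f"NMB @ {e.wtp:,.0f} (EUR)": [e.nmb()[s] for s in STRATEGIES],
            },
            index=list(STRATEGIES),
        )
        lines = [
            "Cost-utility analysis (discounted)",
            df.round({"QALYs": 3, "Cost (EUR)": 0, f"NMB @ {e.wtp:,.0f} (EUR)": 0}).to_string(),
            "",
            f"Incremental QALYs : {e.delta_qaly:.3f}",
            f"Incremental cost  : EUR {e.delta_cost:,.0f}",
        ]
        if math.isnan(e.icer):
            lines.append("ICER              : undefined (zero incremental effect)")
        else:
            lines.append(f"ICER              : EUR {e.icer:,.0f}/QALY")
        if e.dominance:
            lines.append(f"Dominance         : {e.dominance}")
        return "\n".join(lines)

    def plot_trace(self, strategy: str = "surgery", ax=None):
        """State occupancy over cycles for one strategy."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        trace = self.traces[strategy]
        for k, s in enumerate(trace.states):
            ax.plot(np.arange(trace.occupancy.shape[0]), trace.occupancy[:, k], label=s)
        ax.set_xlabel("cycle (year)")
        ax.set_ylabel("occupancy")
        ax.set_title(f"Cohort trace — {strategy}")
        ax.legend(fontsize="small")
        return ax


@dataclass(frozen=True)
class PSAResults:
    """PSA results with acceptability/EVPI curves hanging off them."""

    model: MarkovCEA
    raw: PSAResult
    specs: dict

    @property
    def n_iter(self) -> int:
        return self.raw.n_iter

    @property
    def seed(self):
        return self.raw.seed

    def summary(self, wtp: float | None = None) -> dict:
        lam = self.model.params.wtp if wtp is None else wtp
        return psa_summary(self.raw, lam)

    def summary_text(self, wtp: float | None = None) -> str:
        s = self.summary(wtp)
        df = pd.DataFrame(
            {
                "mean QALYs": s["mean_qalys"],
                "mean cost (EUR)": s["mean_costs"],
                "mean NMB (EUR)": s["mean_nmb"],
            }
        )
        lines = [
            f"Probabilistic sensitivity analysis ({s['n_iter']} iterations, "
            f"{s['n_rejected']} rejected draws)",
            df.round(3).to_string(),
            "",
            f"Mean incremental QALYs : {s['mean_delta_qaly']:.3f}",
            f"Mean incremental cost  : EUR {s['mean_delta_cost']:,.0f}",
            f"ICER (ratio of means)  : EUR {s['icer']:,.0f}/QALY",
        ]
        return "\n".join(lines)

    def wtp_grid(self) -> np.ndarray:
        return make_wtp_grid(include=self.model.params.wtp)

    def ceac(self, grid: np.ndarray | None = None) -> np.ndarray:
        return ceac(self.raw, self.wtp_grid() if grid is None else grid)

    def ceaf(self, grid: np.ndarray | None = None):
        return ceaf(self.raw, self.wtp_grid() if grid is None else grid)

    def evpi(self, grid: np.ndarray | None = None) -> np.ndarray:
        return evpi(self.raw, self.wtp_grid() if grid is None else grid)

    def voi_curves(self, grid: np.ndarray | None = None) -> pd.DataFrame:
        return voi_curves(self.raw, self.wtp_grid() if grid is None else grid)

    def to_frame(self) -> pd.DataFrame:
        return self.raw.to_frame()

    def manifest(self) -> dict:
        return self.raw.manifest(self.specs)

    def plot_ce_plane(self, ax=None):
        """Incremental cost vs incremental effect scatter with the WTP line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d_cost, d_qaly = self.raw.incremental()
        ax.scatter(d_qaly, d_cost, s=6, alpha=0.4)
        lam = self.model.params.wtp
        xs = np.array([min(d_qaly.min(), 0), max(d_qaly.max(), 0)])
        ax.plot(xs, lam * xs, color="k", lw=1, label=f"λ = €{lam:,.0f}/QALY")
        ax.axhline(0, color="gray", lw=0.5)
        ax.axvline(0, color="gray", lw=0.5)
        ax.set_xlabel("incremental QALYs")
        ax.set_ylabel("incremental cost (€)")
        ax.legend()
        return ax

    def plot_ceac(self, grid: np.ndarray | None = None, ax=None):
        """CEACs of both strategies plus the acceptability frontier."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = self.wtp_grid() if grid is None else grid
        acc = self.ceac(grid)
        for k, s in enumerate(self.raw.strategies):
            ax.plot(grid, acc[:, k], label=f"CEAC {s}")
        _, front = self.ceaf(grid)
        ax.plot(grid, front, "k--", lw=1, label="CEAF")
        ax.set_xlabel("willingness to pay (€/QALY)")
        ax.set_ylabel("probability cost-effective")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        return ax

    def plot_evpi(self, grid: np.ndarray | None = None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = self.wtp_grid() if grid is None else grid
        ax.plot(grid, self.evpi(grid))
        ax.set_xlabel("willingness to pay (€/QALY)")
        ax.set_ylabel("EVPI (€ per patient)")
        return ax
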