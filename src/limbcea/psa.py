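"""Probabilistic sensitivity analysis: sample the uncertain parameters,
rerun the whole model per draw, and collect per-iteration costs and effects.

Sampling is Monte Carlo with a fixed parameter order
(:data:`limbcea.distributions.SAMPLING_ORDER`) so a seed fully determines
the draw stream. A draw that makes a surgical-window transition row
infeasible (stated outflows > 1) is rejected and redrawn, and the rejection
count is retained on the result; clamping would silently distort the
sampled distribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._run import STRATEGIES, run_strategy
from .distributions import SAMPLING_ORDER, DistributionSpec, default_specs
from .lifetables import LifeTable, MortalityAdjustment
from .parameters import ModelParameters
from .transitions import StructuralError
from .valuation import INTERVENTION, REFERENCE, icer

__all__ = ["PSAResult", "run_psa", "psa_summary"]

log = logging.getLogger(__name__)

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration discounted (cost, QALY) pairs per strategy.

    ``costs`` and ``qalys`` have shape ``(n_iter, 2)`` with columns ordered
    (no_treatment, surgery). ``samples`` retains each iteration's sampled
    parameter set.
    """

    costs: np.ndarray
    qalys: np.ndarray
    strategies: tuple = STRATEGIES
    samples: pd.DataFrame | None = None
    seed: int | None = None
    n_rejected: int = 0

    @property
    def n_iter(self) -> int:
        return self.costs.shape[0]

    def nmb(self, wtp: float) -> np.ndarray:
        """Per-iteration net monetary benefit, shape (n_iter, 2)."""
        return wtp * self.qalys - self.costs

    def incremental(self) -> tuple[np.ndarray, np.ndarray]:
        """(delta_cost, delta_qaly) per iteration, surgery minus no treatment."""
        j = self.strategies.index(INTERVENTION)
        i = self.strategies.index(REFERENCE)
        return self.costs[:, j] - self.costs[:, i], self.qalys[:, j] - self.qalys[:, i]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, s in enumerate(self.strategies):
            rows.append(
                pd.DataFrame(
                    {
                        "iter": np.arange(self.n_iter),
                        "strategy": s,
                        "cost": self.costs[:, k],
                        "qaly": self.qalys[:, k],
                    }
                )
            )
        return pd.concat(rows).sort_values(["iter", "strategy"]).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def manifest(self, specs: dict | None = None) -> dict:
        m = {"n_iter": self.n_iter, "seed": self.seed, "n_rejected": self.n_rejected}
        if specs is not None:
            m["specs"] = {k: v.to_dict() for k, v in specs.items()}
        return m


def _draw_params(
    base: ModelParameters, specs: dict, rng: np.random.Generator
) -> tuple[ModelParameters, dict]:
    values = {}
    for name in SAMPLING_ORDER:
        spec = specs.get(name)
        if spec is None:
            continue
        values[name] = float(spec.sample(rng))
    return base.update(**values), values


def run_psa(
    params: ModelParameters,
    life: LifeTable,
    n_iter: int = 1000,
    seed: int | None = None,
    specs: dict | None = None,
    adj: MortalityAdjustment | None = None,
) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty through both strategies.

    Parameters
    ----------
    params : ModelParameters
        Base case; parameters without a spec are held at these values.
    specs : dict name -> DistributionSpec, optional
        Defaults to :func:`limbcea.distributions.default_specs`.
    seed : int, optional
        Seeds a fresh :class:`numpy.random.Generator`; identical seeds give
        bit-identical results.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    if specs is None:
        specs = default_specs(params)
    unknown = set(specs) - set(SAMPLING_ORDER)
    if unknown:
        raise ValueError(f"specs for unknown parameters: {sorted(unknown)}")
    if adj is None:
        adj = MortalityAdjustment(surgical_mortality=params.surg_dp)
    rng = np.random.default_rng(seed)

    costs = np.empty((n_iter, len(STRATEGIES)))
    qalys = np.empty((n_iter, len(STRATEGIES)))
    sample_rows = []
    n_rejected = 0
    for it in range(n_iter):
        for attempt in range(_MAX_REDRAWS):
            drawn, values = _draw_params(params, specs, rng)
            # surgical mortality stays at the drawn/base value inside adj
            adj_it = MortalityAdjustment(
                age_shift=adj.age_shift, surgical_mortality=drawn.surg_dp
            )
            try:
                for k, strategy in enumerate(STRATEGIES):
                    _, q, c = run_strategy(drawn, life, adj_it, strategy)
                    qalys[it, k] = q
                    costs[it, k] = c
            except StructuralError:
                n_rejected += 1
                continue
            break
        else:
            raise StructuralError(
                f"iteration {it}: {_MAX_REDRAWS} consecutive draws produced infeasible "
                "transition rows; check the distribution specs"
            )
        sample_rows.append(values)

    if n_rejected:
        log.info("PSA rejected and redrew %d infeasible parameter draws", n_rejected)
    samples = pd.DataFrame(sample_rows)
    samples.insert(0, "iter", np.arange(n_iter))
    return PSAResult(
        costs=costs,
        qalys=qalys,
        samples=samples,
        seed=seed,
        n_rejected=n_rejected,
    )


def psa_summary(result: PSAResult, wtp: float) -> dict:
    """Mean costs/QALYs per strategy, mean increments, ICER of means, mean NMB.

    The PSA ICER is the ratio of mean incremental cost to mean incremental
    effect (ratio of means, not mean of per-iteration ratios, which is
    unstable when incremental effects cross zero).
    """
    if result.n_iter == 0:
        raise ValueError("empty PSA result")
    mean_costs = result.costs.mean(axis=0)
    mean_qalys = result.qalys.mean(axis=0)
    d_cost, d_qaly = result.incremental()
    mean_nmb = result.nmb(wtp).mean(axis=0)
    s = dict(zip(result.strategies, range(len(result.strategies))))
    return {
        "mean_qalys": {k: float(mean_qalys[i]) for k, i in s.items()},
        "mean_costs": {k: float(mean_costs[i]) for k, i in s.items()},
        "mean_delta_qaly": float(d_qaly.mean()),
        "mean_delta_cost": float(d_cost.mean()),
        "icer": icer(float(d_cost.mean()), float(d_qaly.mean())),
        "mean_nmb": {k: float(mean_nmb[i]) for k, i in s.items()},
        "wtp": wtp,
        "n_iter": result.n_iter,
        "n_rejected": result.n_rejected,
    }
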