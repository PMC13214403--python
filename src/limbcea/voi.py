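"""Decision-uncertainty curves over a willingness-to-pay grid: the
cost-effectiveness acceptability curve (CEAC), the acceptability frontier
(CEAF) and the expected value of perfect information (EVPI).

All three are computed from the same PSA sample of per-iteration net
monetary benefits NMB(λ) = λ·QALYs − cost:

- CEAC: per λ, the fraction of iterations in which each strategy attains
  the maximal NMB.
- CEAF: per λ, the strategy with the highest *mean* NMB, reported with its
  acceptability; the frontier switches strategies exactly at the ICER of
  means.
- EVPI: per λ, E[max_s NMB_s] − max_s E[NMB_s], the expected gain from a
  perfectly informed decision, in € per patient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .psa import PSAResult

__all__ = ["make_wtp_grid", "ceac", "ceaf", "evpi", "voi_curves"]


def make_wtp_grid(
    start: float = 0.0,
    stop: float = 50000.0,
    step: float = 500.0,
    include: float | None = 25000.0,
) -> np.ndarray:
    """Ascending λ grid (€/QALY); guarantees ``include`` is a grid point."""
    if step <= 0 or stop <= start or start < 0:
        raise ValueError("grid must be ascending and nonnegative")
    grid = np.arange(start, stop + step / 2, step, dtype=float)
    if include is not None and not np.any(np.isclose(grid, include)):
        grid = np.sort(np.append(grid, float(include)))
    return grid


def _winners(result: PSAResult, lam: float) -> np.ndarray:
    """Index of the max-NMB strategy per iteration; ties go to the
    reference strategy (index 0), deterministically."""
    nmb = result.nmb(lam)
    best = nmb.max(axis=1, keepdims=True)
    is_best = nmb >= best  # ties flagged for every tying strategy
    return np.argmax(is_best, axis=1)  # first (reference-most) winner


def ceac(result: PSAResult, grid: np.ndarray) -> np.ndarray:
    """Acceptability per (λ, strategy): shape (len(grid), n_strategies);
    rows sum to 1."""
    n_s = len(result.strategies)
    out = np.empty((len(grid), n_s))
    for i, lam in enumerate(grid):
        w = _winners(result, float(lam))
        out[i] = np.bincount(w, minlength=n_s) / result.n_iter
    return out


def ceaf(result: PSAResult, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Frontier: per λ, (index of the strategy with maximal mean NMB, its
    CEAC value). Mean-NMB ties go to the reference strategy."""
    acc = ceac(result, grid)
    idx = np.empty(len(grid), dtype=int)
    for i, lam in enumerate(grid):
        mean_nmb = result.nmb(float(lam)).mean(axis=0)
        # argmax of reversed tie -> prefer lowest index on ties
        idx[i] = int(np.argmax(mean_nmb >= mean_nmb.max()))
    return idx, acc[np.arange(len(grid)), idx]


def evpi(result: PSAResult, grid: np.ndarray) -> np.ndarray:
    """Per-patient EVPI(λ) = E[max_s NMB_s(λ)] − max_s E[NMB_s(λ)], in €."""
    out = np.empty(len(grid))
    for i, lam in enumerate(grid):
        nmb = result.nmb(float(lam))
        out[i] = nmb.max(axis=1).mean() - nmb.mean(axis=0).max()
    # clip tiny negative round-off; the quantity is >= 0 by Jensen's inequality
    return np.maximum(out, 0.0)


def voi_curves(result: PSAResult, grid: np.ndarray) -> pd.DataFrame:
    """All three curves in one frame:
    ``lambda, p_<strategy>..., frontier_strategy, frontier_p, evpi``."""
    acc = ceac(result, grid)
    idx, front_p = ceaf(result, grid)
    df = pd.DataFrame({"lambda": grid})
    for k, s in enumerate(result.strategies):
        df[f"p_{s}"] = acc[:, k]
    df["frontier_strategy"] = [result.strategies[i] for i in idx]
    df["frontier_p"] = front_p
    df["evpi"] = evpi(result, grid)
    return df
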