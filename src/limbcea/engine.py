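"""Cohort propagation: push an occupancy distribution through the
cycle-indexed transition matrices and record the trace.

Convention: the occupancy at cycle ``t`` is the distribution of states
being *lived* during cycle ``t``; the cycle-``t`` matrix is applied at the
end of that cycle. A run over ``n`` matrices therefore yields ``n + 1``
occupancy rows, the last being the terminal distribution after the final
transition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CohortTrace", "run_trace"]

_MASS_TOL = 1e-10


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy proportions per cycle for one strategy.

    ``occupancy`` has shape ``(n_cycles + 1, n_states)``; row ``t`` is the
    distribution lived during cycle ``t`` (row 0 is the initial state).
    """

    occupancy: np.ndarray
    states: tuple
    strategy: str = ""
    start_age: int = 0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "states", tuple(self.states))
        if occ.ndim != 2 or occ.shape[1] != len(self.states):
            raise ValueError("occupancy must be (cycles+1, n_states)")
        if np.any(occ < -_MASS_TOL):
            raise ValueError("negative occupancy in trace")
        sums = occ.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _MASS_TOL):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"occupancy at cycle {bad} sums to {sums[bad]!r}, expected 1")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def state_column(self, state: str) -> np.ndarray:
        return self.occupancy[:, self.states.index(state)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.insert(0, "age", self.start_age + np.arange(self.occupancy.shape[0]))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_trace(
    initial: Sequence[float],
    matrices: np.ndarray,
    states: Sequence[str],
    strategy: str = "",
    start_age: int = 0,
) -> CohortTrace:
    """Propagate ``initial`` through the matrix sequence.

    Parameters
    ----------
    initial : vector summing to 1
        Occupancy at cycle 0.
    matrices : array (n_cycles, S, S)
        One row-stochastic matrix per cycle.
    states : sequence of str
        State labels, in matrix order.
    """
    initial = np.asarray(initial, dtype=float)
    matrices = np.asarray(matrices, dtype=float)
    if matrices.ndim != 3 or matrices.shape[1] != matrices.shape[2]:
        raise ValueError(f"matrices must have shape (n, S, S), got {matrices.shape}")
    if matrices.shape[0] == 0:
        raise ValueError("matrix sequence is empty")
    if initial.shape != (matrices.shape[1],):
        raise ValueError(
            f"initial occupancy has length {initial.shape}, matrices are {matrices.shape[1]}-state"
        )
    if abs(initial.sum() - 1.0) > _MASS_TOL:
        raise ValueError(f"initial occupancy sums to {initial.sum()!r}, expected 1")
    if len(states) != matrices.shape[1]:
        raise ValueError("state labels do not match matrix dimension")

    n = matrices.shape[0]
    occ = np.empty((n + 1, matrices.shape[1]))
    occ[0] = initial
    for t in range(n):
        occ[t + 1] = occ[t] @ matrices[t]
    return CohortTrace(occupancy=occ, states=tuple(states), strategy=strategy, start_age=start_age)
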