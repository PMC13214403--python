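"""State spaces and cycle-indexed transition matrices for the two strategies.

No-treatment strategy: {NormalLife, Death}. Surgery strategy: the cohort
enters lower-limb lengthening (LLL), may suffer a complication (LLComp),
may continue to upper-limb lengthening (ULL, with its own complication
state ULComp) or withdraw after the lower-limb stage, and ends in one of
two lifelong states that differ only in the utility they earn:
NormalLifeLLLOnly (lower limbs lengthened, withdrew before the upper-limb
stage) and NormalLifeFull (both stages completed). The printed transition
structure has a single "normal life" destination; splitting it into two
bookkeeping states with identical transition rows makes the path-dependent
lifelong utility assignable in a memoryless chain (the two columns sum to
the single printed column).

Surgical states are structurally transient: a cohort that starts wholly in
LLL vacates all four surgical states within 4 transitions (longest path
LLL → LLComp → ULL → ULComp → normal life), whatever the parameter values.
The as-printed surgical rows are therefore built — and their probability
constraints enforced — only for cycles inside that window; at later cycles
the unreachable surgical rows are replaced by a valid absorbing placeholder
so every matrix stays row-stochastic even when background mortality at high
ages would make the printed formulas infeasible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lifetables import LifeTable, MortalityAdjustment, dp_at
from .parameters import ModelParameters

__all__ = [
    "NO_TREATMENT_STATES",
    "SURGERY_STATES",
    "SURGICAL_STATES",
    "SURGICAL_WINDOW",
    "StructuralError",
    "TransitionParams",
    "build_no_treatment_matrix",
    "build_surgery_matrix",
    "matrix_sequence",
    "validate_matrix",
]

NO_TREATMENT_STATES = ("NormalLife", "Death")
SURGERY_STATES = (
    "LLL",
    "LLComp",
    "ULL",
    "ULComp",
    "NormalLifeLLLOnly",
    "NormalLifeFull",
    "Death",
)
#: states in which the cohort is undergoing (or recovering from) surgery
SURGICAL_STATES = ("LLL", "LLComp", "ULL", "ULComp")
#: cycles after which surgical states are provably empty when the cohort starts in LLL
SURGICAL_WINDOW = 4

_ROW_TOL = 1e-12


class StructuralError(ValueError):
    """A transition row's stated outflows are infeasible (sum > 1)."""


@dataclass(frozen=True)
class TransitionParams:
    """Per-cycle probabilities entering the surgery-strategy matrix."""

    p_ll_comp: float
    p_ul_comp: float
    p_withdraw: float
    dp: float
    surg_dp: float

    def __post_init__(self) -> None:
        for name in ("p_ll_comp", "p_ul_comp", "p_withdraw", "dp", "surg_dp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def build_no_treatment_matrix(dp: float) -> np.ndarray:
    """2×2 matrix over (NormalLife, Death): [[1-dp, dp], [0, 1]]."""
    if not 0.0 <= dp <= 1.0:
        raise ValueError(f"dp must be in [0, 1], got {dp}")
    return np.array([[1.0 - dp, dp], [0.0, 1.0]])


def _check_outflow(row_label: str, outflow: float) -> None:
    if outflow > 1.0 + _ROW_TOL:
        raise StructuralError(
            f"row {row_label}: stated outflows sum to {outflow:.6g} > 1; "
            "the transition probabilities are jointly infeasible at this cycle"
        )


def build_surgery_matrix(tp: TransitionParams, surgical_active: bool = True) -> np.ndarray:
    """7×7 one-cycle matrix over ``SURGERY_STATES``.

    With ``surgical_active`` (the default), surgical rows follow the printed
    formulas and a :class:`StructuralError` is raised if any row's outflow
    exceeds 1. With ``surgical_active=False`` the (unreachable) surgical
    rows are replaced by unit flows to Death, which keeps the matrix
    row-stochastic without affecting any trace that has already left the
    surgical window.
    """
    n = len(SURGERY_STATES)
    i = {s: k for k, s in enumerate(SURGERY_STATES)}
    M = np.zeros((n, n))
    d, sd = tp.dp, tp.surg_dp

    if surgical_active:
        _check_outflow("LLL", tp.p_ll_comp + d + sd)
        stay_ll = 1.0 - tp.p_ll_comp - d - sd
        M[i["LLL"], i["LLComp"]] = tp.p_ll_comp
        M[i["LLL"], i["ULL"]] = stay_ll * (1.0 - tp.p_withdraw)
        M[i["LLL"], i["NormalLifeLLLOnly"]] = stay_ll * tp.p_withdraw
        M[i["LLL"], i["Death"]] = d + sd

        _check_outflow("LLComp", d + sd)
        alive_llc = 1.0 - d - sd
        M[i["LLComp"], i["ULL"]] = alive_llc * (1.0 - tp.p_withdraw)
        M[i["LLComp"], i["NormalLifeLLLOnly"]] = alive_llc * tp.p_withdraw
        M[i["LLComp"], i["Death"]] = d + sd

        _check_outflow("ULL", tp.p_ul_comp + d + sd)
        M[i["ULL"], i["ULComp"]] = tp.p_ul_comp
        M[i["ULL"], i["NormalLifeFull"]] = 1.0 - tp.p_ul_comp - d - sd
        M[i["ULL"], i["Death"]] = d + sd

        _check_outflow("ULComp", d + sd)
        M[i["ULComp"], i["NormalLifeFull"]] = 1.0 - d - sd
        M[i["ULComp"], i["Death"]] = d + sd
    else:
        for s in SURGICAL_STATES:
            M[i[s], i["Death"]] = 1.0

    for s in ("NormalLifeLLLOnly", "NormalLifeFull"):
        M[i[s], i[s]] = 1.0 - d
        M[i[s], i["Death"]] = d
    M[i["Death"], i["Death"]] = 1.0
    return M


def validate_matrix(M: np.ndarray, tol: float = _ROW_TOL) -> None:
    """Assert row-stochasticity, entry range, and Death absorption."""
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {M.shape}")
    if np.any(M < -tol) or np.any(M > 1.0 + tol):
        raise ValueError("transition matrix has entries outside [0, 1]")
    rows = M.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > max(tol, 1e-12)):
        bad = int(np.argmax(np.abs(rows - 1.0)))
        raise ValueError(f"row {bad} sums to {rows[bad]!r}, expected 1")
    death = np.zeros(M.shape[0])
    death[-1] = 1.0
    if not np.allclose(M[-1], death):
        raise ValueError("Death (last state) must be absorbing")


def matrix_sequence(
    strategy: str,
    params: ModelParameters,
    life: LifeTable,
    adj: MortalityAdjustment | None = None,
) -> np.ndarray:
    """Per-cycle transition matrices for one strategy, shape (n_cycles, S, S).

    Cycle ``t`` uses the background death probability of age
    ``start_age + t`` (looked up through the age-shifted table); the
    surgical mortality increment enters only the surgical-state rows.
    """
    if adj is None:
        adj = MortalityAdjustment(surgical_mortality=params.surg_dp)
    n = params.n_cycles
    try:
        dps = np.array([dp_at(life, adj, params.start_age + t) for t in range(n)])
    except ValueError as exc:
        raise ValueError(
            f"life table does not cover the full horizon "
            f"(start age {params.start_age}, {n} cycles, shift {adj.age_shift}): {exc}"
        ) from exc

    if strategy == "no_treatment":
        out = np.stack([build_no_treatment_matrix(d) for d in dps])
    elif strategy == "surgery":
        mats = []
        for t, d in enumerate(dps):
            tp = TransitionParams(
                p_ll_comp=params.p_ll_comp,
                p_ul_comp=params.p_ul_comp,
                p_withdraw=params.p_withdraw,
                dp=float(d),
                surg_dp=params.surg_dp,
            )
            try:
                mats.append(build_surgery_matrix(tp, surgical_active=t < SURGICAL_WINDOW))
            except StructuralError as exc:
                raise StructuralError(f"cycle {t} (age {params.start_age + t}): {exc}") from exc
        out = np.stack(mats)
    else:
        raise ValueError(f"unknown strategy {strategy!r}; use 'no_treatment' or 'surgery'")
    return out
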