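import numpy as np
import pytest

from limbcea import (
    LifeTable,
    MarkovCEA,
    ModelParameters,
    MortalityAdjustment,
    gompertz_makeham_table,
)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return gompertz_makeham_table()


@pytest.fixture(scope="session")
def adjustment(params) -> MortalityAdjustment:
    return MortalityAdjustment(surgical_mortality=params.surg_dp)


@pytest.fixture(scope="session")
def model(params, life_table, adjustment) -> MarkovCEA:
    return MarkovCEA(params=params, life_table=life_table, adjustment=adjustment)


@pytest.fixture(scope="session")
def base_results(model):
    return model.fit()


@pytest.fixture(scope="session")
def psa_results(model):
    """One shared 1,000-iteration PSA (the study's configured size)."""
    return model.fit_psa(n_iter=1000, seed=20260921)


def constant_table(qx_value: float, max_age: int = 200) -> LifeTable:
    """A flat-mortality table (closure forced at max_age)."""
    qx = np.full(max_age + 1, qx_value, dtype=float)
    qx[-1] = 1.0
    return LifeTable(ages=np.arange(max_age + 1), qx=qx)


def microsimulate(matrices: np.ndarray, initial_state: int, n_individuals: int, seed: int):
    """Individual-level Monte Carlo oracle for the cohort engine.

    Simulates ``n_individuals`` independent trajectories through the cycle
    matrices and returns per-cycle state frequencies, shape
    ``(n_cycles + 1, n_states)``.
    """
    rng = np.random.default_rng(seed)
    n_cycles, n_states, _ = matrices.shape
    state = np.full(n_individuals, initial_state, dtype=np.int64)
    freq = np.zeros((n_cycles + 1, n_states))
    freq[0] = np.bincount(state, minlength=n_states) / n_individuals
    for t in range(n_cycles):
        cum = np.cumsum(matrices[t], axis=1)
        u = rng.random(n_individuals)
        state = (u[:, None] > cum[state]).sum(axis=1)
        freq[t + 1] = np.bincount(state, minlength=n_states) / n_individuals
    return freq
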