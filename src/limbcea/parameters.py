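"""Model parameters: utilities, disutility multipliers, transition
probabilities, procedure costs, discounting and structural settings.

Defaults are the base case of the evaluation: EQ-5D-Y utilities for
non-lengthened individuals (0.711), lower-limb-lengthened (0.888) and fully
lengthened (0.944) patients; disutility multipliers for the surgery and
complication years; per-procedure costs in euros; 3% annual discounting on
both costs and health; a €25,000/QALY willingness-to-pay threshold; and a
90-cycle (year) horizon starting at age 12.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = ["ModelParameters"]

_PROBABILITIES = ("p_ll_comp", "p_ul_comp", "p_withdraw", "surg_dp")
_UTILITIES = ("u_base", "u_lll", "u_full")
_MULTIPLIERS = ("m_lll", "m_ull", "m_llc", "m_ulc")
_COSTS = ("c_lll", "c_ull", "c_comp")


@dataclass(frozen=True)
class ModelParameters:
    """Every tunable quantity of the cost-utility model.

    Attributes
    ----------
    u_base, u_lll, u_full : float
        Lifelong utilities: untreated, lower-limb lengthening only, and
        lower+upper lengthening.
    sd_u_base, sd_u_lll, sd_u_full : float
        Standard deviations of the utilities (used only by the PSA's
        moment-matched beta distributions).
    m_lll, m_ull, m_llc, m_ulc : float
        Utility multipliers applied during the lower-limb surgery,
        upper-limb surgery, lower-limb complication and upper-limb
        complication years.
    c_lll, c_ull, c_comp : float
        Mean procedure costs (€): lower-limb lengthening, upper-limb
        lengthening, and one complication reoperation.
    p_ll_comp, p_ul_comp : float
        Probability of a complication (reoperation) after lower- and
        upper-limb lengthening.
    p_withdraw : float
        Probability of discontinuing after the lower-limb stage (ending
        with lower limbs lengthened only).
    surg_dp : float
        Per-cycle probability of dying during elective surgery, added to
        background mortality in surgical states.
    r_cost, r_health : float
        Annual discount rates on costs and on health outcomes.
    wtp : float
        Willingness-to-pay threshold (€/QALY) for net-monetary-benefit
        summaries.
    start_age : int
        Cohort age at cycle 0.
    n_cycles : int
        Number of year-long cycles.
    incident_cases_per_year : int
        New eligible patients per year (budget impact).
    multiplier_base : str
        Which utility each disutility multiplier scales: ``"pathway"``
        (default) multiplies the post-stage utility of that pathway
        (u_lll for lower-limb states, u_full for upper-limb states);
        ``"baseline"`` multiplies u_base instead.
    psa_ess : float
        Effective sample size of the beta distributions used for
        probabilities and multipliers in the PSA.
    psa_cost_cv : float
        Coefficient of variation of the gamma distributions used for
        costs in the PSA.
    """

    u_base: float = 0.711
    u_lll: float = 0.888
    u_full: float = 0.944
    sd_u_base: float = 0.266
    sd_u_lll: float = 0.111
    sd_u_full: float = 0.078
    m_lll: float = 0.7
    m_ull: float = 0.8
    m_llc: float = 0.8
    m_ulc: float = 0.75
    c_lll: float = 28539.0
    c_ull: float = 10834.0
    c_comp: float = 6275.0
    p_ll_comp: float = 0.8
    p_ul_comp: float = 0.1
    p_withdraw: float = 0.1
    surg_dp: float = 0.00013
    r_cost: float = 0.03
    r_health: float = 0.03
    wtp: float = 25000.0
    start_age: int = 12
    n_cycles: int = 90
    incident_cases_per_year: int = 15
    multiplier_base: str = "pathway"
    psa_ess: float = 50.0
    psa_cost_cv: float = 0.30

    def __post_init__(self) -> None:
        for name in _UTILITIES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"utility {name} must be in [0, 1], got {v}")
        for name in _MULTIPLIERS:
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"multiplier {name} must be in (0, 1], got {v}")
        for name in _COSTS:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"cost {name} must be >= 0, got {v}")
        for name in _PROBABILITIES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"probability {name} must be in [0, 1], got {v}")
        for name in ("r_cost", "r_health"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"discount rate {name} must be in [0, 1), got {v}")
        if self.wtp < 0:
            raise ValueError(f"wtp must be >= 0, got {self.wtp}")
        if self.start_age < 0:
            raise ValueError(f"start_age must be >= 0, got {self.start_age}")
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.incident_cases_per_year < 0:
            raise ValueError(
                f"incident_cases_per_year must be >= 0, got {self.incident_cases_per_year}"
            )
        if self.multiplier_base not in ("pathway", "baseline"):
            raise ValueError(
                f"multiplier_base must be 'pathway' or 'baseline', got {self.multiplier_base!r}"
            )
        if self.psa_ess <= 0:
            raise ValueError(f"psa_ess must be > 0, got {self.psa_ess}")
        if self.psa_cost_cv <= 0:
            raise ValueError(f"psa_cost_cv must be > 0, got {self.psa_cost_cv}")

    def update(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
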