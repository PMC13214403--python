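"""Parameter-uncertainty distributions for the probabilistic sensitivity
analysis: moment-matched betas for utilities, effective-sample-size betas
for probabilities and multipliers, and coefficient-of-variation gammas for
costs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "DistributionSpec",
    "beta_from_moments",
    "beta_from_ess",
    "gamma_from_cv",
    "default_specs",
    "SAMPLING_ORDER",
]

log = logging.getLogger(__name__)


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta parameters for a given mean and sd.

    With ν = mean(1−mean)/sd² − 1: alpha = mean·ν, beta = (1−mean)·ν.
    Requires 0 < mean < 1 and sd² < mean(1−mean); at the boundary ν = 0 and
    no beta distribution has those moments.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0, 1), got {mean}")
    if sd <= 0:
        raise ValueError(f"beta sd must be > 0, got {sd}")
    var_max = mean * (1.0 - mean)
    if sd * sd >= var_max:
        raise ValueError(
            f"infeasible beta moments: sd²={sd * sd:.6g} must be < mean(1-mean)={var_max:.6g}"
        )
    nu = var_max / (sd * sd) - 1.0
    alpha, beta = mean * nu, (1.0 - mean) * nu
    if alpha < 1.0 or beta < 1.0:
        log.warning(
            "beta(mean=%.3f, sd=%.3f) -> alpha=%.4f, beta=%.4f: a U-adjacent shape; "
            "the stated moments sit near the feasibility edge and are used as given",
            mean, sd, alpha, beta,
        )
    return alpha, beta


def beta_from_ess(mean: float, ess: float) -> tuple[float, float]:
    """Beta parameters from a mean and an effective sample size:
    alpha = mean·ess, beta = (1−mean)·ess."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0, 1), got {mean}")
    if ess <= 0:
        raise ValueError(f"effective sample size must be > 0, got {ess}")
    return mean * ess, (1.0 - mean) * ess


def gamma_from_cv(mean: float, cv: float) -> tuple[float, float]:
    """Gamma (shape, scale) from a mean and coefficient of variation:
    shape = 1/cv², scale = mean·cv² (implied sd = mean·cv)."""
    if mean <= 0:
        raise ValueError(f"gamma mean must be > 0, got {mean}")
    if cv <= 0:
        raise ValueError(f"coefficient of variation must be > 0, got {cv}")
    return 1.0 / (cv * cv), mean * cv * cv


_FAMILIES = ("beta-mm", "beta-ess", "gamma-cv", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """One sampled parameter's distribution.

    family:
      - ``"beta-mm"``  — beta matched to (mean, sd)
      - ``"beta-ess"`` — beta from (mean, effective sample size)
      - ``"gamma-cv"`` — gamma from (mean, coefficient of variation)
      - ``"fixed"``    — degenerate at ``mean`` (not sampled)
    """

    family: str
    mean: float
    sd: float | None = None
    ess: float | None = None
    cv: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        # validate eagerly (and warn at most once) by caching the natural params
        object.__setattr__(self, "_nat", self._derive_natural_params())

    def _natural_params(self):
        return self._nat

    def _derive_natural_params(self):
        if self.family == "beta-mm":
            if self.sd is None:
                raise ValueError("beta-mm requires sd")
            return beta_from_moments(self.mean, self.sd)
        if self.family == "beta-ess":
            if self.ess is None:
                raise ValueError("beta-ess requires ess")
            return beta_from_ess(self.mean, self.ess)
        if self.family == "gamma-cv":
            if self.cv is None:
                raise ValueError("gamma-cv requires cv")
            return gamma_from_cv(self.mean, self.cv)
        return None

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the spec; ``fixed`` returns the mean."""
        if self.family == "fixed":
            return self.mean if size is None else np.full(size, self.mean)
        p, q = self._natural_params()
        if self.family in ("beta-mm", "beta-ess"):
            return rng.beta(p, q, size=size)
        return rng.gamma(shape=p, scale=q, size=size)

    def implied_sd(self) -> float:
        if self.family == "fixed":
            return 0.0
        if self.family == "beta-mm":
            return float(self.sd)
        if self.family == "beta-ess":
            a, b = self._natural_params()
            return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0))))
        return self.mean * float(self.cv)

    def to_dict(self) -> dict:
        d = {"family": self.family, "mean": self.mean}
        for k in ("sd", "ess", "cv"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


#: fixed draw order so that a seed fully determines the sample stream
SAMPLING_ORDER = (
    "u_base",
    "u_lll",
    "u_full",
    "m_lll",
    "m_ull",
    "m_llc",
    "m_ulc",
    "p_ll_comp",
    "p_ul_comp",
    "p_withdraw",
    "c_lll",
    "c_ull",
    "c_comp",
)


def default_specs(params: ModelParameters) -> dict:
    """The base-case PSA specification.

    Utilities: moment-matched betas at their published means and sds.
    Multipliers and transition probabilities: betas at a fixed effective
    sample size (no published dispersion). Costs: gammas at a common
    coefficient of variation. Discount rates, mortality and the WTP
    threshold are fixed.
    """
    ess, cv = params.psa_ess, params.psa_cost_cv
    return {
        "u_base": DistributionSpec("beta-mm", params.u_base, sd=params.sd_u_base),
        "u_lll": DistributionSpec("beta-mm", params.u_lll, sd=params.sd_u_lll),
        "u_full": DistributionSpec("beta-mm", params.u_full, sd=params.sd_u_full),
        "m_lll": DistributionSpec("beta-ess", params.m_lll, ess=ess),
        "m_ull": DistributionSpec("beta-ess", params.m_ull, ess=ess),
        "m_llc": DistributionSpec("beta-ess", params.m_llc, ess=ess),
        "m_ulc": DistributionSpec("beta-ess", params.m_ulc, ess=ess),
        "p_ll_comp": DistributionSpec("beta-ess", params.p_ll_comp, ess=ess),
        "p_ul_comp": DistributionSpec("beta-ess", params.p_ul_comp, ess=ess),
        "p_withdraw": DistributionSpec("beta-ess", params.p_withdraw, ess=ess),
        "c_lll": DistributionSpec("gamma-cv", params.c_lll, cv=cv),
        "c_ull": DistributionSpec("gamma-cv", params.c_ull, cv=cv),
        "c_comp": DistributionSpec("gamma-cv", params.c_comp, cv=cv),
    }
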