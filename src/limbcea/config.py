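"""Run configuration: schema, loading, validation and orchestration.

A run config is a YAML or JSON file with optional blocks ``model``,
``life_table``, ``mortality``, ``psa``, ``wtp_grid`` and ``budget``; every
missing value falls back to the base case, and unknown keys are rejected.
``run_all`` executes base case → PSA → VOI → budget impact and writes all
artifacts plus a manifest echoing the effective configuration.
"""

from __future__ import annotations

import json
import logging
import os
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .budget import BudgetScenario, per_patient_cost_stream, run_budget
from .distributions import SAMPLING_ORDER, DistributionSpec, default_specs
from .lifetables import LifeTable, MortalityAdjustment, gompertz_makeham_table, read_life_table
from .parameters import ModelParameters
from .voi import make_wtp_grid

__all__ = ["RunConfig", "load_config", "build_model", "run_all"]

log = logging.getLogger(__name__)


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelBlock(_Block):
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

    def to_params(self) -> ModelParameters:
        # ModelParameters re-validates ranges and raises the domain messages
        return ModelParameters(**self.model_dump())

    @model_validator(mode="after")
    def _domain_ranges(self):
        self.to_params()  # raises ValueError with the offending key named
        return self


class GompertzMakehamBlock(_Block):
    a: float = 5e-4
    b: float = 3.5e-5
    c: float = 1.095
    max_age: int = 120


class LifeTableBlock(_Block):
    path: str | None = None
    gompertz_makeham: GompertzMakehamBlock = Field(default_factory=GompertzMakehamBlock)


class MortalityBlock(_Block):
    age_shift: int = 10


class DistOverride(_Block):
    family: str
    mean: float
    sd: float | None = None
    ess: float | None = None
    cv: float | None = None

    def to_spec(self) -> DistributionSpec:
        return DistributionSpec(
            family=self.family, mean=self.mean, sd=self.sd, ess=self.ess, cv=self.cv
        )


class PSABlock(_Block):
    n_iter: int = 1000
    seed: int | None = None
    overrides: dict[str, DistOverride] = Field(default_factory=dict)

    @field_validator("overrides")
    @classmethod
    def _known_params(cls, v):
        unknown = set(v) - set(SAMPLING_ORDER)
        if unknown:
            raise ValueError(f"distribution overrides for unknown parameters: {sorted(unknown)}")
        return v


class WTPGridBlock(_Block):
    start: float = 0.0
    stop: float = 50000.0
    step: float = 500.0


class BudgetBlock(_Block):
    horizon_years: int = 15
    patients_per_year: float = 15
    patients_per_year_50pct: float = 7
    discount_rate: float = 0.03
    bia_discounting: str = "program_start"


class RunConfig(_Block):
    model: ModelBlock = Field(default_factory=ModelBlock)
    life_table: LifeTableBlock = Field(default_factory=LifeTableBlock)
    mortality: MortalityBlock = Field(default_factory=MortalityBlock)
    psa: PSABlock = Field(default_factory=PSABlock)
    wtp_grid: WTPGridBlock = Field(default_factory=WTPGridBlock)
    budget: BudgetBlock = Field(default_factory=BudgetBlock)
    output_dir: str = "limbcea-output"

    def effective(self) -> dict:
        """Every effective value, defaults resolved — the manifest echo."""
        return self.model_dump()


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config; an empty file gives full defaults."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).lower().endswith(".json"):
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return RunConfig.model_validate(data)


def build_life_table(config: RunConfig) -> LifeTable:
    lt = config.life_table
    if lt.path:
        return read_life_table(lt.path)
    gm = lt.gompertz_makeham
    return gompertz_makeham_table(a=gm.a, b=gm.b, c=gm.c, max_age=gm.max_age)


def build_model(config: RunConfig):
    from .model import MarkovCEA

    params = config.model.to_params()
    adj = MortalityAdjustment(
        age_shift=config.mortality.age_shift, surgical_mortality=params.surg_dp
    )
    return MarkovCEA(params=params, life_table=build_life_table(config), adjustment=adj)


def _pkg_version() -> str:
    try:
        return version("limbcea")
    except PackageNotFoundError:
        return "unknown"


def run_all(
    config: RunConfig, out_dir=None, seed: int | None = None, n_iter: int | None = None
) -> dict:
    """Execute the full pipeline and write every artifact.

    Returns a dict of output paths. ``seed``/``n_iter`` override the config's
    PSA block (convenient for CLI flags).
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = build_model(config)
    params = model.params
    psa_seed = config.psa.seed if seed is None else seed
    psa_n = config.psa.n_iter if n_iter is None else n_iter

    paths = {}

    log.info("stage: base case")
    base = model.fit()
    for strategy, trace in base.traces.items():
        p = out / f"trace_{strategy}.csv"
        trace.to_csv(p)
        paths[f"trace_{strategy}"] = str(p)
    p = out / "base_case.json"
    base.econ.to_json(p)
    paths["base_case"] = str(p)
    (out / "base_case.txt").write_text(base.summary() + "\n", encoding="utf-8")
    paths["base_case_text"] = str(out / "base_case.txt")

    log.info("stage: PSA (%d iterations, seed %r)", psa_n, psa_seed)
    specs = default_specs(params)
    specs.update({k: v.to_spec() for k, v in config.psa.overrides.items()})
    psa = model.fit_psa(n_iter=psa_n, seed=psa_seed, specs=specs)
    p = out / "psa_samples.csv"
    psa.raw.to_csv(p)
    paths["psa_samples"] = str(p)
    p = out / "psa_parameters.csv"
    psa.raw.samples.to_csv(p, index=False)
    paths["psa_parameters"] = str(p)
    p = out / "psa_summary.json"
    p.write_text(json.dumps(psa.summary(), indent=2), encoding="utf-8")
    paths["psa_summary"] = str(p)

    log.info("stage: VOI curves")
    grid = make_wtp_grid(
        config.wtp_grid.start, config.wtp_grid.stop, config.wtp_grid.step, include=params.wtp
    )
    p = out / "voi_curves.csv"
    psa.voi_curves(grid).to_csv(p, index=False)
    paths["voi_curves"] = str(p)

    log.info("stage: budget impact")
    stream = per_patient_cost_stream(params, model.life_table, model.adjustment)
    for label, n_pat in (
        ("full", config.budget.patients_per_year),
        ("50pct", config.budget.patients_per_year_50pct),
    ):
        scenario = BudgetScenario(
            horizon_years=config.budget.horizon_years,
            patients_per_year=n_pat,
            discount_rate=config.budget.discount_rate,
            discounting=config.budget.bia_discounting,
            uptake_label=label,
        )
        res = run_budget(scenario, stream)
        p = out / f"budget_{label}.csv"
        res.to_csv(p)
        paths[f"budget_{label}"] = str(p)

    manifest = {
        "package_version": _pkg_version(),
        "numpy_version": np.__version__,
        "seed": psa_seed,
        "n_iter": psa_n,
        "psa_rejected_draws": psa.raw.n_rejected,
        "effective_config": config.effective(),
        "psa_specs": {k: v.to_dict() for k, v in specs.items()},
        "outputs": paths,
    }
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    paths["manifest"] = str(p)
    return paths
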