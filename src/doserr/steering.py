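"""Steering-file parsing and validation.

A study is described by one YAML steering file: the dose grid, the
error/truth scenarios, the estimators to run and their settings, the
ensemble sizes and the master seed.  The schema is strict -- unknown
keys are rejected and the whole file validates before any computation.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Literal, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .estimators import ESTIMATORS, McmcSettings
from .evaluation import ScenarioSpec
from .sim_core import DoseGrid, ErrorSpec, RiskModel, default_grid

__all__ = ["SteeringConfig", "load_steering", "SteeringError"]


class SteeringError(ValueError):
    """Invalid steering file."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    group_edges: List[Tuple[float, Optional[float]]]
    central_doses: List[float]
    person_years: List[float]
    n_individuals: List[int]

    def build(self) -> DoseGrid:
        return DoseGrid(
            group_edges=tuple(self.group_edges),
            central_doses=np.array(self.central_doses),
            person_years=np.array(self.person_years),
            n_individuals=np.array(self.n_individuals),
        )


class ScenarioConfig(_Strict):
    name: str
    sigma_shared_berkson: float = 0.0
    sigma_unshared_berkson: float = 0.0
    sigma_shared_classical: float = 0.0
    sigma_unshared_classical: float = 0.0
    alpha: float
    beta: float = 0.0
    form: Literal["linear", "linear-quadratic"]

    @field_validator(
        "sigma_shared_berkson",
        "sigma_unshared_berkson",
        "sigma_shared_classical",
        "sigma_unshared_classical",
    )
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("error SDs must be non-negative")
        return v


class McmcConfig(_Strict):
    n_chains: int = 2
    n_burnin: int = 1000
    n_keep: int = 1000
    proposal_sd_kappa: float = 0.2
    proposal_sd_coef: float = 1.0
    proposal_sd_lambda: float = 2.0
    lambda_block: int = 10
    prior_sd: float = 1000.0
    bgr_threshold: float = 1.05

    def build(self) -> McmcSettings:
        return McmcSettings(**self.model_dump())


class FmaConfig(_Strict):
    k_samples: int = 100
    symmetric_sd: bool = True


class EnsembleConfig(_Strict):
    n_meta: int = Field(ge=1)
    m_sub: int = Field(ge=1)
    n_cases: int = Field(default=250, ge=1)


class SteeringConfig(_Strict):
    """Fully validated study description."""

    scenarios: List[ScenarioConfig]
    methods: List[str]
    ensemble: EnsembleConfig
    seed: int = 0
    grid: Optional[GridConfig] = None
    mcmc: McmcConfig = Field(default_factory=McmcConfig)
    fma: FmaConfig = Field(default_factory=FmaConfig)
    output_dir: str = "results"

    @model_validator(mode="after")
    def _check(self):
        if not self.scenarios:
            raise ValueError("at least one scenario is required")
        if not self.methods:
            raise ValueError("at least one estimator method is required")
        unknown = [m for m in self.methods if m not in ESTIMATORS]
        if unknown:
            raise ValueError(f"unknown estimator(s) {unknown}; known: {sorted(ESTIMATORS)}")
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            raise ValueError("scenario names must be unique")
        return self

    def to_scenario_specs(self, seed_override: Optional[int] = None) -> List[ScenarioSpec]:
        grid = self.grid.build() if self.grid is not None else default_grid()
        seed = self.seed if seed_override is None else seed_override
        specs = []
        for i, sc in enumerate(self.scenarios):
            specs.append(
                ScenarioSpec(
                    name=sc.name,
                    errors=ErrorSpec(
                        sigma_shared_berkson=sc.sigma_shared_berkson,
                        sigma_unshared_berkson=sc.sigma_unshared_berkson,
                        sigma_shared_classical=sc.sigma_shared_classical,
                        sigma_unshared_classical=sc.sigma_unshared_classical,
                    ),
                    truth=RiskModel(alpha=sc.alpha, beta=sc.beta),
                    form=sc.form,
                    methods=tuple(self.methods),
                    n_meta=self.ensemble.n_meta,
                    m_sub=self.ensemble.m_sub,
                    n_cases=self.ensemble.n_cases,
                    grid=grid,
                    seed=seed + i,
                    mcmc=self.mcmc.build(),
                    fma_k_samples=self.fma.k_samples,
                    fma_symmetric_sd=self.fma.symmetric_sd,
                )
            )
        return specs


def load_steering(path) -> SteeringConfig:
    """Parse and fully validate a YAML steering file; raises
    :class:`SteeringError` with a descriptive message on any problem."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise SteeringError(f"cannot read steering file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise SteeringError(f"steering file {path} must be a mapping of sections")
    try:
        cfg = SteeringConfig.model_validate(raw)
    except Exception as exc:
        raise SteeringError(f"invalid steering file {path}:\n{exc}") from exc
    try:
        cfg.to_scenario_specs()
    except Exception as exc:
        raise SteeringError(f"invalid steering file {path}: {exc}") from exc
    return cfg
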