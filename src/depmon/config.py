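"""Run configuration: validation, defaults, overrides and file round-trips.

A single :class:`RunConfig` (YAML or JSON on disk) drives the whole
pipeline; one ``seed`` governs every stochastic component, with per-component
sub-seeds derived deterministically from it.  All monetary values are
abstract currency units.  The shipped defaults are documented placeholders
with realistic magnitudes, not transcriptions of any proprietary data set.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .cohort_prep import RiskGroupProfile, prepare_cohort, profiles_from_json
from .economics import EconomicParams
from .engine import EngineOptions, ModelParams, TreatmentLine
from .strategies import StrategySpec, default_strategies
from .synthetic_cohort import default_spec, generate_cohort

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "apply_overrides",
    "build_profiles",
    "component_seed",
]


class UtilitiesCfg(BaseModel):
    H: float = 0.85
    M: float = 0.72
    S: float = 0.58

    @field_validator("H", "M", "S")
    @classmethod
    def _in_unit(cls, v, info):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"utility({info.field_name}) must be in [0, 1], got {v}")
        return v

    @model_validator(mode="after")
    def _ordered(self):
        if not (self.H >= self.M >= self.S):
            raise ValueError(
                f"utility ordering violated: need utilities.H >= utilities.M >= "
                f"utilities.S, got H={self.H}, M={self.M}, S={self.S}"
            )
        return self


class EconomicsCfg(BaseModel):
    utilities: UtilitiesCfg = Field(default_factory=UtilitiesCfg)
    followup_visit_cost: float = Field(180.0, ge=0)
    background_treatment_cost: float = Field(40.0, ge=0)
    treatment_change_cost: float = Field(0.0, ge=0)
    annual_discount_rate: float = Field(0.03, ge=0)
    wtp_threshold: float = Field(81_630.0, ge=0)


class ModelCfg(BaseModel):
    horizon_months: int = Field(24, ge=1)
    monthly_mortality: float = Field(0.0004, ge=0, le=1)
    annual_followup_dropout: float = Field(0.20, ge=0, le=1)


class LineCfg(BaseModel):
    pr_rm: float = Field(ge=0, le=1)
    pr_rsp: float = Field(ge=0, le=1)
    monthly_cost: float = Field(ge=0)
    adverse_discontinuation: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _boost_budget(self):
        if self.pr_rm + self.pr_rsp > 1.0 + 1e-12:
            raise ValueError(
                f"pr_rm + pr_rsp must be <= 1, got {self.pr_rm} + {self.pr_rsp}"
            )
        return self


def _default_lines() -> list[LineCfg]:
    pr_rm = [0.35, 0.30, 0.26, 0.22, 0.19, 0.16, 0.13, 0.11, 0.09]
    pr_rsp = [0.20, 0.18, 0.16, 0.14, 0.13, 0.12, 0.11, 0.10, 0.09]
    cost = [25.0, 30.0, 40.0, 55.0, 70.0, 85.0, 100.0, 115.0, 130.0]
    adverse = [0.06, 0.07, 0.08, 0.09, 0.10, 0.11, 0.12, 0.13, 0.14]
    return [
        LineCfg(
            pr_rm=pr_rm[i],
            pr_rsp=pr_rsp[i],
            monthly_cost=cost[i],
            adverse_discontinuation=adverse[i],
        )
        for i in range(9)
    ]


class AdaptiveCfg(BaseModel):
    sensitivity: float = Field(0.85, ge=0, le=1)
    specificity: float = Field(0.85, ge=0, le=1)
    monitoring_cost_monthly: float = Field(12.0, ge=0)


class EngineCfg(BaseModel):
    visits_per_year_overrides: dict[str, float] = Field(default_factory=dict)
    suppress_lockout_visits: bool = False


class PrepCfg(BaseModel):
    min_observations: int = Field(6, ge=1)
    ewma_alpha: float = Field(0.5, gt=0, le=1)
    n_clusters: int = Field(3, ge=1)
    kmeans_restarts: int = Field(20, ge=1)
    zero_row_fallback: Literal["self_loop", "uniform"] = "self_loop"


class SyntheticCfg(BaseModel):
    n_patients: int = Field(444, ge=1)
    score_noise_sd: float = Field(1.2, ge=0)
    missing_fraction: float = Field(0.38, ge=0, lt=1)
    female_fraction: float = Field(0.69, ge=0, le=1)
    mean_age: float = Field(45.0, gt=0)


class ScalesCfg(BaseModel):
    """Multiplicative scenario knobs over the nine treatment lines."""

    line_cost: float = Field(1.0, ge=0)
    pr_rm: float = Field(1.0, ge=0)
    pr_rsp: float = Field(1.0, ge=0)
    adverse: float = Field(1.0, ge=0)


class SensitivityCfg(BaseModel):
    cost_levels: list[float] = Field(default_factory=lambda: [0.0, 12.0, 50.0])
    grid_points: int = Field(11, ge=2)


class RunConfig(BaseModel):
    seed: int = 12345
    model: ModelCfg = Field(default_factory=ModelCfg)
    economics: EconomicsCfg = Field(default_factory=EconomicsCfg)
    lines: list[LineCfg] = Field(default_factory=_default_lines)
    adaptive: AdaptiveCfg = Field(default_factory=AdaptiveCfg)
    engine: EngineCfg = Field(default_factory=EngineCfg)
    prep: PrepCfg = Field(default_factory=PrepCfg)
    synthetic: SyntheticCfg = Field(default_factory=SyntheticCfg)
    scales: ScalesCfg = Field(default_factory=ScalesCfg)
    sensitivity: SensitivityCfg = Field(default_factory=SensitivityCfg)
    profiles_path: str | None = None
    output_dir: str = "outputs"

    @field_validator("lines")
    @classmethod
    def _nine_lines(cls, v):
        if len(v) != 9:
            raise ValueError(f"exactly 9 treatment lines required, got {len(v)}")
        return v

    # ---- builders to domain objects -------------------------------------

    def model_params(self) -> ModelParams:
        return ModelParams(
            horizon_months=self.model.horizon_months,
            monthly_mortality=self.model.monthly_mortality,
            annual_followup_dropout=self.model.annual_followup_dropout,
            annual_discount_rate=self.economics.annual_discount_rate,
        )

    def economic_params(self) -> EconomicParams:
        u = self.economics.utilities
        return EconomicParams(
            utility_per_level={"H": u.H, "M": u.M, "S": u.S},
            followup_visit_cost=self.economics.followup_visit_cost,
            background_treatment_cost=self.economics.background_treatment_cost,
            treatment_change_cost=self.economics.treatment_change_cost,
            annual_discount_rate=self.economics.annual_discount_rate,
            wtp_threshold=self.economics.wtp_threshold,
        )

    def treatment_lines(self) -> list[TreatmentLine]:
        s = self.scales
        out = []
        for i, ln in enumerate(self.lines):
            rm = min(ln.pr_rm * s.pr_rm, 1.0)
            rsp = min(ln.pr_rsp * s.pr_rsp, 1.0)
            if rm + rsp > 1.0:  # preserve the ratio when scaling overshoots
                f = 1.0 / (rm + rsp)
                rm, rsp = rm * f, rsp * f
            out.append(
                TreatmentLine(
                    index=i + 1,
                    pr_rm=rm,
                    pr_rsp=rsp,
                    monthly_cost=ln.monthly_cost * s.line_cost,
                    adverse_discontinuation=min(
                        ln.adverse_discontinuation * s.adverse, 1.0
                    ),
                )
            )
        return out

    def engine_options(self) -> EngineOptions:
        return EngineOptions(
            visits_per_year_overrides=dict(self.engine.visits_per_year_overrides),
            suppress_lockout_visits=self.engine.suppress_lockout_visits,
        )

    def adaptive_strategy(self) -> StrategySpec:
        a = self.adaptive
        return StrategySpec(
            kind="adaptive",
            sensitivity=a.sensitivity,
            specificity=a.specificity,
            monitoring_cost_monthly=a.monitoring_cost_monthly,
        )

    def strategy_presets(self) -> list[StrategySpec]:
        a = self.adaptive
        return default_strategies(
            sensitivity=a.sensitivity,
            specificity=a.specificity,
            monitoring_cost_monthly=a.monitoring_cost_monthly,
        )


_COMPONENT_IDS = {"synthetic": 1, "prep": 2, "microsim": 3}


def component_seed(seed: int, component: str) -> int:
    """Stable sub-seed (independent of Python hash randomization)."""
    return int(
        np.random.SeedSequence([seed, _COMPONENT_IDS.get(component, 0)])
        .generate_state(1)[0]
        % (2**31)
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config; defaults fill absent fields."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} not found")
    text = path.read_text()
    try:
        payload = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValueError(f"cannot parse config {path}: {exc}") from exc
    return RunConfig(**(payload or {}))


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    payload = config.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def apply_overrides(config: RunConfig, overrides: dict[str, float]) -> RunConfig:
    """Return a new config with dot-path overrides applied and re-validated."""
    if not overrides:
        return config
    payload = config.model_dump()
    for path, value in overrides.items():
        node = payload
        parts = path.split(".")
        for part in parts[:-1]:
            if isinstance(node, list):
                node = node[int(part)]
            elif isinstance(node, dict) and part in node:
                node = node[part]
            else:
                raise KeyError(f"override path {path!r} does not resolve")
        leaf = parts[-1]
        if isinstance(node, list):
            node[int(leaf)] = value
        elif isinstance(node, dict) and leaf in node:
            node[leaf] = value
        else:
            raise KeyError(f"override path {path!r} does not resolve")
    return RunConfig(**payload)


def build_profiles(config: RunConfig) -> list[RiskGroupProfile]:
    """Risk-group profiles: from disk if configured, else synth + prep chain."""
    if config.profiles_path:
        return profiles_from_json(config.profiles_path)
    spec = default_spec(
        n_patients=config.synthetic.n_patients,
        seed=component_seed(config.seed, "synthetic"),
    )
    spec.score_noise_sd = config.synthetic.score_noise_sd
    spec.missing_fraction = config.synthetic.missing_fraction
    spec.female_fraction = config.synthetic.female_fraction
    spec.mean_age = config.synthetic.mean_age
    records, _ = generate_cohort(spec)
    profiles, _, _ = prepare_cohort(
        records,
        min_observations=config.prep.min_observations,
        ewma_alpha=config.prep.ewma_alpha,
        n_clusters=config.prep.n_clusters,
        seed=component_seed(config.seed, "prep"),
        n_restarts=config.prep.kmeans_restarts,
        zero_row_fallback=config.prep.zero_row_fallback,
    )
    return profiles
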