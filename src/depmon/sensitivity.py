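"""Deterministic sensitivity machinery.

Two layers, mirroring how a health-technology assessment interrogates an
emerging monitoring technology:

* a **technology grid**: every combination of sensitivity and specificity on
  an 11-point 0..1 grid, a small set of monthly monitoring costs and the
  risk groups (11 x 11 x 3 x 3 = 1089 cells by default).  Each cell compares
  the adaptive technology against the rule-based comparator under otherwise
  identical parameters and classifies it as dominated, cost-saving or by its
  ICER -- the data behind the heat maps.
* **scenario sweeps**: one-way, two-way and multi-way overrides of the
  non-technology parameters, each re-simulated per risk group, with the
  fraction of cost-effective scenarios summarized per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort_prep import RiskGroupProfile
from .economics import (
    CEAResult,
    EconomicParams,
    accrue,
    classify_vs_comparator,
)
from .engine import EngineOptions, ModelParams, TreatmentLine, simulate
from .strategies import StrategySpec

__all__ = [
    "TechGridSpec",
    "HeatMapCell",
    "ScenarioSpec",
    "run_tech_grid",
    "cells_to_frame",
    "heatmap_matrix",
    "run_scenarios",
    "default_scenarios",
    "load_scenarios_yaml",
    "save_scenarios_yaml",
    "render_heatmaps",
]

DEFAULT_ACCURACY_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))


@dataclass
class TechGridSpec:
    """The sensitivity x specificity x cost x risk-group grid."""

    groups: list[RiskGroupProfile]
    sensitivity_grid: Sequence[float] = DEFAULT_ACCURACY_GRID
    specificity_grid: Sequence[float] = DEFAULT_ACCURACY_GRID
    cost_levels: Sequence[float] = (0.0, 12.0, 50.0)

    def __post_init__(self) -> None:
        for name in ("sensitivity_grid", "specificity_grid"):
            g = list(getattr(self, name))
            if not g or any(not (0.0 <= v <= 1.0) for v in g):
                raise ValueError(f"{name} must be non-empty with values in [0, 1]")
            if any(b <= a for a, b in zip(g, g[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if not self.cost_levels or any(c < 0 for c in self.cost_levels):
            raise ValueError("cost_levels must be non-empty and non-negative")
        if not self.groups:
            raise ValueError("need at least one risk group")

    @property
    def n_cells(self) -> int:
        return (
            len(self.sensitivity_grid)
            * len(self.specificity_grid)
            * len(self.cost_levels)
            * len(self.groups)
        )


@dataclass
class HeatMapCell:
    group: str
    cost_level: float
    sensitivity: float
    specificity: float
    outcome: str  # dominated | cost_saving | icer
    icer: float | None
    cost_effective: bool
    tech_cost: float
    tech_qaly: float
    comparator_cost: float
    comparator_qaly: float


def run_tech_grid(
    spec: TechGridSpec,
    lines: list[TreatmentLine],
    params: ModelParams,
    econ: EconomicParams,
    options: EngineOptions | None = None,
) -> list[HeatMapCell]:
    """Evaluate every grid cell against the rule-based comparator.

    The comparator is simulated once per group; only the adaptive strategy's
    technology factors vary across cells.  Deterministic and independent of
    evaluation order.
    """
    cells: list[HeatMapCell] = []
    rule = StrategySpec(kind="rule_based")
    for profile in spec.groups:
        rres = simulate(profile, rule, lines, params, options)
        rcost, rqaly = accrue(rres, rule, lines, econ, params)
        comparator = CEAResult(strategy=rule, total_cost=rcost, total_qaly=rqaly)
        for cost_level in spec.cost_levels:
            for sens in spec.sensitivity_grid:
                for spc in spec.specificity_grid:
                    adaptive = StrategySpec(
                        kind="adaptive",
                        sensitivity=float(sens),
                        specificity=float(spc),
                        monitoring_cost_monthly=float(cost_level),
                    )
                    ares = simulate(profile, adaptive, lines, params, options)
                    acost, aqaly = accrue(ares, adaptive, lines, econ, params)
                    tech = CEAResult(
                        strategy=adaptive, total_cost=acost, total_qaly=aqaly
                    )
                    cls = classify_vs_comparator(tech, comparator, econ.wtp_threshold)
                    cells.append(
                        HeatMapCell(
                            group=profile.name,
                            cost_level=float(cost_level),
                            sensitivity=float(sens),
                            specificity=float(spc),
                            outcome=cls["outcome"],
                            icer=cls["icer"],
                            cost_effective=cls["cost_effective"],
                            tech_cost=acost,
                            tech_qaly=aqaly,
                            comparator_cost=rcost,
                            comparator_qaly=rqaly,
                        )
                    )
    return cells


def cells_to_frame(cells: Sequence[HeatMapCell]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [c.group for c in cells],
            "cost_level": [c.cost_level for c in cells],
            "sensitivity": [c.sensitivity for c in cells],
            "specificity": [c.specificity for c in cells],
            "outcome": [c.outcome for c in cells],
            "icer_value": [c.icer if c.icer is not None else "" for c in cells],
            "cost_effective": [c.cost_effective for c in cells],
            "tech_cost": [c.tech_cost for c in cells],
            "tech_qaly": [c.tech_qaly for c in cells],
            "comparator_cost": [c.comparator_cost for c in cells],
            "comparator_qaly": [c.comparator_qaly for c in cells],
        }
    )


def heatmap_matrix(
    cells: Sequence[HeatMapCell], group: str, cost_level: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract one (group, cost) slice as matrices indexed (sens row, spec col).

    Returns ``(sens_values, spec_values, outcome_codes, icer_values)``; ICER
    entries are NaN where the cell is dominated or cost-saving.
    """
    sel = [c for c in cells if c.group == group and c.cost_level == cost_level]
    if not sel:
        raise ValueError(f"no cells for group {group!r} at cost level {cost_level!r}")
    sens = np.array(sorted({c.sensitivity for c in sel}))
    spec = np.array(sorted({c.specificity for c in sel}))
    if len(sel) != len(sens) * len(spec):
        raise ValueError("incomplete grid slice")
    outcome = np.empty((len(sens), len(spec)), dtype=object)
    icers = np.full((len(sens), len(spec)), np.nan)
    si = {v: i for i, v in enumerate(sens)}
    pj = {v: j for j, v in enumerate(spec)}
    for c in sel:
        i, j = si[c.sensitivity], pj[c.specificity]
        outcome[i, j] = c.outcome
        if c.icer is not None and np.isfinite(c.icer):
            icers[i, j] = c.icer
    return sens, spec, outcome, icers


def render_heatmaps(cells, wtp: float, out_dir, cost_levels=None, groups=None):
    """Optional PNG heat maps (diverging scale centered at the WTP threshold)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups = groups or sorted({c.group for c in cells})
    cost_levels = cost_levels or sorted({c.cost_level for c in cells})
    paths = []
    for cost in cost_levels:
        fig, axes = plt.subplots(1, len(groups), figsize=(5 * len(groups), 4))
        axes = np.atleast_1d(axes)
        for ax, g in zip(axes, groups):
            sens, spec, outcome, icers = heatmap_matrix(cells, g, cost)
            shown = np.clip(icers, 0, 2 * wtp)
            im = ax.imshow(
                shown,
                origin="lower",
                cmap="RdBu_r",
                vmin=0,
                vmax=2 * wtp,
                extent=(spec[0], spec[-1], sens[0], sens[-1]),
                aspect="auto",
            )
            dom = np.array(outcome == "dominated", dtype=float)
            dom[dom == 0] = np.nan
            ax.imshow(
                dom,
                origin="lower",
                cmap="Greys",
                vmin=0,
                vmax=1.5,
                extent=(spec[0], spec[-1], sens[0], sens[-1]),
                aspect="auto",
            )
            ax.set_title(f"{g} risk (monitoring ${cost:g}/mo)")
            ax.set_xlabel("specificity")
            ax.set_ylabel("sensitivity")
        fig.colorbar(im, ax=axes, label="ICER vs rule-based ($/QALY)")
        path = out_dir / f"heatmap_cost_{cost:g}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# scenario sweeps


@dataclass
class ScenarioSpec:
    """Named bundle of parameter overrides (dot paths into the run config)."""

    label: str
    overrides: dict[str, float] = field(default_factory=dict)


#: one-way low/high values per parameter; documented placeholder ranges, not
#: transcribed from any external source.
ONE_WAY_RANGES: dict[str, tuple[float, float]] = {
    "model.monthly_mortality": (0.0002, 0.0008),
    "model.annual_followup_dropout": (0.10, 0.30),
    "economics.annual_discount_rate": (0.0, 0.05),
    "economics.followup_visit_cost": (90.0, 360.0),
    "economics.background_treatment_cost": (20.0, 80.0),
    "economics.utilities.H": (0.80, 0.92),
    "economics.utilities.M": (0.66, 0.78),
    "economics.utilities.S": (0.50, 0.64),
    "scales.line_cost": (0.5, 2.0),
    "scales.pr_rm": (0.5, 1.5),
    "scales.pr_rsp": (0.5, 1.5),
    "scales.adverse": (0.5, 2.0),
}

#: parameters crossed pairwise in the two-way block.
TWO_WAY_PARAMS = (
    "economics.followup_visit_cost",
    "economics.background_treatment_cost",
    "scales.line_cost",
    "scales.pr_rm",
    "model.annual_followup_dropout",
    "model.monthly_mortality",
)


def default_scenarios() -> list[ScenarioSpec]:
    """97 scenarios: base + 24 one-way + 60 two-way + 12 multi-way.

    The structure (one-way low/high per parameter, pairwise crosses of the
    six most influential parameters, and a dozen multi-way bundles) mirrors a
    standard deterministic sensitivity-analysis design; the numeric ranges
    are this package's documented placeholders.
    """
    scenarios = [ScenarioSpec(label="base_case")]
    for path, (lo, hi) in ONE_WAY_RANGES.items():
        short = path.split(".")[-1] if not path.startswith("scales") else path
        scenarios.append(ScenarioSpec(f"{short}_low", {path: lo}))
        scenarios.append(ScenarioSpec(f"{short}_high", {path: hi}))
    for i, a in enumerate(TWO_WAY_PARAMS):
        for b in TWO_WAY_PARAMS[i + 1 :]:
            for da, db in (("low", "low"), ("low", "high"), ("high", "low"),
                           ("high", "high")):
                va = ONE_WAY_RANGES[a][0 if da == "low" else 1]
                vb = ONE_WAY_RANGES[b][0 if db == "low" else 1]
                label = f"{a.split('.')[-1]}_{da}__{b.split('.')[-1]}_{db}"
                scenarios.append(ScenarioSpec(label, {a: va, b: vb}))
    multi = [
        ("treatment_optimistic",
         {"scales.pr_rm": 1.5, "scales.pr_rsp": 1.5, "scales.adverse": 0.5}),
        ("treatment_pessimistic",
         {"scales.pr_rm": 0.5, "scales.pr_rsp": 0.5, "scales.adverse": 2.0}),
        ("care_cheap",
         {"economics.followup_visit_cost": 90.0,
          "economics.background_treatment_cost": 20.0, "scales.line_cost": 0.5}),
        ("care_expensive",
         {"economics.followup_visit_cost": 360.0,
          "economics.background_treatment_cost": 80.0, "scales.line_cost": 2.0}),
        ("engagement_poor",
         {"model.annual_followup_dropout": 0.30, "scales.adverse": 2.0}),
        ("engagement_good",
         {"model.annual_followup_dropout": 0.10, "scales.adverse": 0.5}),
        ("qol_compressed",
         {"economics.utilities.H": 0.80, "economics.utilities.M": 0.74,
          "economics.utilities.S": 0.64}),
        ("qol_spread",
         {"economics.utilities.H": 0.92, "economics.utilities.M": 0.70,
          "economics.utilities.S": 0.50}),
        ("worst_case",
         {"scales.pr_rm": 0.5, "scales.pr_rsp": 0.5,
          "economics.followup_visit_cost": 90.0,
          "model.annual_followup_dropout": 0.30, "scales.adverse": 2.0}),
        ("best_case",
         {"scales.pr_rm": 1.5, "scales.pr_rsp": 1.5,
          "economics.followup_visit_cost": 360.0,
          "model.annual_followup_dropout": 0.10, "scales.adverse": 0.5}),
        ("undiscounted_cheap_treatment",
         {"economics.annual_discount_rate": 0.0, "scales.line_cost": 0.5}),
        ("high_mortality_severe_qol",
         {"model.monthly_mortality": 0.0008, "economics.utilities.S": 0.50}),
    ]
    scenarios += [ScenarioSpec(lbl, ov) for lbl, ov in multi]
    return scenarios


def load_scenarios_yaml(path) -> list[ScenarioSpec]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    out = []
    for item in payload:
        out.append(
            ScenarioSpec(
                label=str(item["label"]),
                overrides={str(k): float(v)
                           for k, v in (item.get("overrides") or {}).items()},
            )
        )
    return out


def save_scenarios_yaml(scenarios: Sequence[ScenarioSpec], path) -> None:
    payload = [
        {"label": s.label, "overrides": dict(s.overrides)} for s in scenarios
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def run_scenarios(
    scenarios: Sequence[ScenarioSpec],
    config,
    profiles: list[RiskGroupProfile] | None = None,
    wtp: float | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Re-simulate adaptive vs rule-based per scenario and risk group.

    ``config`` is a :class:`depmon.config.RunConfig`; unresolvable override
    paths raise naming the path.  Returns the per-(scenario, group) outcome
    table and the fraction of cost-effective scenarios per group.
    """
    from .config import apply_overrides, build_profiles

    if profiles is None:
        profiles = build_profiles(config)
    wtp = wtp if wtp is not None else config.economics.wtp_threshold
    rule = StrategySpec(kind="rule_based")
    rows = []
    for sc in scenarios:
        cfg = apply_overrides(config, sc.overrides)
        lines = cfg.treatment_lines()
        params = cfg.model_params()
        econ = cfg.economic_params()
        options = cfg.engine_options()
        adaptive = cfg.adaptive_strategy()
        for profile in profiles:
            rres = simulate(profile, rule, lines, params, options)
            rcost, rqaly = accrue(rres, rule, lines, econ, params)
            ares = simulate(profile, adaptive, lines, params, options)
            acost, aqaly = accrue(ares, adaptive, lines, econ, params)
            cls = classify_vs_comparator(
                CEAResult(strategy=adaptive, total_cost=acost, total_qaly=aqaly),
                CEAResult(strategy=rule, total_cost=rcost, total_qaly=rqaly),
                wtp,
            )
            rows.append(
                {
                    "group": profile.name,
                    "scenario_label": sc.label,
                    "cost": acost,
                    "qaly": aqaly,
                    "comparator_cost": rcost,
                    "comparator_qaly": rqaly,
                    "outcome": cls["outcome"],
                    "icer_value": cls["icer"] if cls["icer"] is not None else "",
                    "cost_effective": cls["cost_effective"],
                }
            )
    table = pd.DataFrame(rows)
    fractions = {
        g: float(grp["cost_effective"].mean())
        for g, grp in table.groupby("group", sort=False)
    }
    return table, fractions
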