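"""Discounted cost/QALY accrual, ICERs, efficiency frontier and dominance.

Costs are taken from the payer perspective: follow-up visit fees, background
treatment (drug) cost, the active treatment line's monthly cost (the
exhausted stratum is charged the average of the nine line costs), an optional
per-change switching fee and the adaptive technology's monthly monitoring
fee.  Utilities attach to the current-month severity level and QALYs accrue
at 1/12 of the annual utility per cycle.  Discounting uses
``(1 + r)^(-(m - 1)/12)`` so the first cycle is undiscounted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import ModelParams, SimulationResult, TreatmentLine, EngineOptions, simulate
from .model_core import PAIR_CODES
from .strategies import StrategySpec

__all__ = [
    "EconomicParams",
    "CEAResult",
    "discount_factor",
    "accrue",
    "icer",
    "Dominated",
    "efficiency_frontier",
    "classify_vs_comparator",
    "evaluate_strategies",
]


@dataclass
class EconomicParams:
    """Utilities (per year, by severity level) and unit costs."""

    utility_per_level: dict[str, float] = field(
        default_factory=lambda: {"H": 0.85, "M": 0.72, "S": 0.58}
    )
    followup_visit_cost: float = 180.0
    background_treatment_cost: float = 40.0
    treatment_change_cost: float = 0.0
    annual_discount_rate: float = 0.03
    wtp_threshold: float = 81_630.0

    def __post_init__(self) -> None:
        u = self.utility_per_level
        if set(u) != {"H", "M", "S"}:
            raise ValueError("utility_per_level must map exactly H, M, S")
        for k, v in u.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"utility({k}) must be in [0, 1], got {v}")
        if not (u["H"] >= u["M"] >= u["S"]):
            raise ValueError(
                "utilities must satisfy utility(H) >= utility(M) >= utility(S), "
                f"got H={u['H']}, M={u['M']}, S={u['S']}"
            )
        for f in (
            "followup_visit_cost",
            "background_treatment_cost",
            "treatment_change_cost",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.annual_discount_rate < 0 or self.wtp_threshold < 0:
            raise ValueError("discount rate and WTP threshold must be >= 0")


def discount_factor(month: int, annual_rate: float) -> float:
    """Monthly discount factor; cycle 1 is undiscounted."""
    if month < 1:
        raise ValueError("month must be >= 1")
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    return (1.0 + annual_rate) ** (-(month - 1) / 12.0)


def accrue(
    result: SimulationResult,
    strategy: StrategySpec,
    lines: list[TreatmentLine],
    econ: EconomicParams,
    params: ModelParams,
) -> tuple[float, float]:
    """Total discounted cost and QALYs of one simulated strategy."""
    util = np.array([econ.utility_per_level[PAIR_CODES[p][1]] for p in range(9)])
    line_cost = np.array([ln.monthly_cost for ln in lines])
    avg_line_cost = float(line_cost.mean())
    monitoring = (
        strategy.monitoring_cost_monthly if strategy.kind == "adaptive" else 0.0
    )
    h = params.horizon_months
    months = np.arange(1, h + 1)
    df = (1.0 + econ.annual_discount_rate) ** (-(months - 1) / 12.0)

    qaly = float(np.sum(df * (result.pair_mass @ util) / 12.0))
    cost_per_cycle = (
        result.attend * econ.followup_visit_cost
        + result.alive * econ.background_treatment_cost
        + result.tx_line_mass @ line_cost
        + result.exhausted_alive * avg_line_cost
        + result.change * econ.treatment_change_cost
        + result.engaged_alive * monitoring
    )
    cost = float(np.sum(df * cost_per_cycle))
    return cost, qaly


@dataclass
class CEAResult:
    strategy: StrategySpec
    total_cost: float
    total_qaly: float
    dominance: str = "frontier"  # frontier | dominated | extended_dominated
    icer_vs_next: float | None = None  # vs the next-cheaper frontier member

    @property
    def label(self) -> str:
        return self.strategy.label


class Dominated(Exception):
    """Signals that an ICER is undefined because the increment is dominated."""


def icer(costly: CEAResult, cheaper: CEAResult) -> float:
    """Incremental cost per QALY of ``costly`` over ``cheaper``."""
    if costly.total_cost < cheaper.total_cost:
        raise ValueError("icer() expects costly.total_cost >= cheaper.total_cost")
    dq = costly.total_qaly - cheaper.total_qaly
    dc = costly.total_cost - cheaper.total_cost
    if dq <= 0:
        raise Dominated(
            f"{costly.label} gains no QALYs over {cheaper.label} (dQALY={dq:g})"
        )
    return dc / dq


def efficiency_frontier(results: list[CEAResult]) -> list[CEAResult]:
    """Annotate dominance and return the frontier in increasing-cost order.

    Strongly dominated strategies (another strategy has no higher cost and no
    lower QALYs, strictly better in one) are removed first; extended-dominated
    strategies (beaten by a mixture of two others, i.e. their incremental ICER
    exceeds the next one along the cost-sorted chain) are then removed
    iteratively until ICERs strictly increase.  Ties in both cost and QALYs
    keep the first-listed strategy on the frontier.
    """
    if not results:
        raise ValueError("need at least one CEAResult")
    for r in results:
        r.dominance = "frontier"
        r.icer_vs_next = None
    for r in results:
        for s in results:
            if s is r:
                continue
            better = (
                s.total_cost <= r.total_cost and s.total_qaly >= r.total_qaly
            )
            strict = s.total_cost < r.total_cost or s.total_qaly > r.total_qaly
            tie = (
                s.total_cost == r.total_cost
                and s.total_qaly == r.total_qaly
                and results.index(s) < results.index(r)
            )
            if better and (strict or tie):
                r.dominance = "dominated"
                break
    frontier = sorted(
        (r for r in results if r.dominance == "frontier"),
        key=lambda r: (r.total_cost, r.total_qaly),
    )
    while len(frontier) > 2:
        icers = [
            icer(frontier[i + 1], frontier[i]) for i in range(len(frontier) - 1)
        ]
        bad = next(
            (i for i in range(len(icers) - 1) if icers[i] >= icers[i + 1]), None
        )
        if bad is None:
            break
        frontier[bad + 1].dominance = "extended_dominated"
        frontier.pop(bad + 1)
    for i, r in enumerate(frontier):
        r.icer_vs_next = None if i == 0 else icer(r, frontier[i - 1])
    return frontier


def classify_vs_comparator(
    tech: CEAResult, comparator: CEAResult, wtp: float
) -> dict:
    """Three-way classification of a technology against its comparator.

    ``dominated`` when the technology yields fewer QALYs; ``cost_saving``
    when it yields at least as many QALYs at strictly lower cost; otherwise
    an ICER (infinite when QALYs are exactly equal at no lower cost) with a
    cost-effectiveness flag at the WTP threshold.
    """
    dq = tech.total_qaly - comparator.total_qaly
    dc = tech.total_cost - comparator.total_cost
    if dq < 0:
        return {"outcome": "dominated", "icer": None, "cost_effective": False}
    if dc < 0:
        return {"outcome": "cost_saving", "icer": None, "cost_effective": True}
    value = math.inf if dq == 0 else dc / dq
    return {"outcome": "icer", "icer": value, "cost_effective": value <= wtp}


def evaluate_strategies(
    profile,
    strategies: list[StrategySpec],
    lines: list[TreatmentLine],
    params: ModelParams,
    econ: EconomicParams,
    options: EngineOptions | None = None,
) -> list[CEAResult]:
    """Simulate and accrue every strategy for one risk group."""
    out = []
    for s in strategies:
        res = simulate(profile, s, lines, params, options)
        cost, qaly = accrue(res, s, lines, econ, params)
        out.append(CEAResult(strategy=s, total_cost=cost, total_qaly=qaly))
    return out
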