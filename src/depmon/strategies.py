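"""Follow-up scheduling strategies.

Five strategies are compared:

* **adaptive** -- remote monitoring assessed every month; patients in a
  needs-change state attend a visit with probability ``sensitivity`` and the
  rest attend unnecessarily with probability ``1 - specificity``.  A monthly
  monitoring fee is charged while the patient stays engaged.
* **rule_based** -- the next visit is booked at the current visit from the
  observed pair state: 2 months for non-response/relapse states, 4 months for
  unstable improvement (SH, SM), 6 months for stable remission (HH, MH).
* **fixed(k)** -- visits every k months (k = 2, 4, 6) regardless of state.

After the nine treatment lines are exhausted, rule-based and fixed schedules
fall back to 6-month maintenance visits; adaptive monitoring keeps charging
its monthly fee but no longer triggers visits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    HealthPairState,
    NEEDS_CHANGE,
    NEEDS_CHANGE_MASK,
    PAIR_CODES,
    STABLE,
    classify_pair,
)

__all__ = [
    "StrategySpec",
    "FollowupDecision",
    "RULE_BASED_INTERVALS",
    "next_followup_rule_based",
    "followup_due_fixed",
    "adaptive_trigger",
    "default_strategies",
]

#: months to next visit by pair-state code under the rule-based schedule.
RULE_BASED_INTERVALS = {
    c: (2 if c in NEEDS_CHANGE else 6 if c in STABLE else 4) for c in PAIR_CODES
}

POST_EXHAUSTION_INTERVAL = 6


@dataclass(frozen=True)
class StrategySpec:
    """Tagged strategy variant: adaptive | rule_based | fixed."""

    kind: str
    sensitivity: float | None = None
    specificity: float | None = None
    monitoring_cost_monthly: float | None = None
    interval_months: int | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "adaptive":
            for f in ("sensitivity", "specificity", "monitoring_cost_monthly"):
                v = getattr(self, f)
                if v is None:
                    raise ValueError(f"adaptive strategy requires {f}")
            for f in ("sensitivity", "specificity"):
                v = getattr(self, f)
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{f} must be in [0, 1], got {v}")
            if self.monitoring_cost_monthly < 0:
                raise ValueError("monitoring_cost_monthly must be >= 0")
        elif self.kind == "fixed":
            if self.interval_months not in (2, 4, 6):
                raise ValueError(
                    f"fixed strategy interval must be 2, 4 or 6 months, "
                    f"got {self.interval_months}"
                )
        elif self.kind != "rule_based":
            raise ValueError(f"unknown strategy kind {self.kind!r}")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        if self.kind == "fixed":
            return f"fixed_{self.interval_months}"
        return self.kind


@dataclass(frozen=True)
class FollowupDecision:
    """Fraction of needs-change / other alive engaged mass attending this month."""

    attend_fraction_needed: float
    attend_fraction_unneeded: float

    def __post_init__(self) -> None:
        for f in (self.attend_fraction_needed, self.attend_fraction_unneeded):
            if not (0.0 <= f <= 1.0):
                raise ValueError("attendance fractions must be in [0, 1]")


def next_followup_rule_based(state: HealthPairState) -> int:
    """Months until the next visit booked from the observed pair state."""
    classify_pair(state)  # validates
    return RULE_BASED_INTERVALS[state.code]


def followup_due_fixed(interval: int, month: int) -> bool:
    """Whether a fixed-frequency visit falls in ``month`` (1-based)."""
    if interval not in (2, 4, 6):
        raise ValueError(f"interval must be 2, 4 or 6, got {interval}")
    if month < 1:
        raise ValueError("month must be >= 1")
    return month % interval == 0


def adaptive_trigger(
    pair_distribution: np.ndarray, sensitivity: float, specificity: float
) -> FollowupDecision:
    """Monthly remote-monitoring trigger applied to engaged, alive mass.

    True-positive detection sends ``sensitivity`` of the needs-change mass to
    a visit; false alarms send ``1 - specificity`` of everyone else.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    d = np.asarray(pair_distribution, dtype=float)
    if d.shape != (9,) or np.any(d < -1e-12) or d.sum() > 1.0 + 1e-9:
        raise ValueError("pair distribution must be non-negative and sum to <= 1")
    return FollowupDecision(
        attend_fraction_needed=sensitivity,
        attend_fraction_unneeded=1.0 - specificity,
    )


def default_strategies(
    sensitivity: float = 0.85,
    specificity: float = 0.85,
    monitoring_cost_monthly: float = 12.0,
) -> list[StrategySpec]:
    """The five compared strategies, adaptive parameters configurable."""
    return [
        StrategySpec(
            kind="adaptive",
            sensitivity=sensitivity,
            specificity=specificity,
            monitoring_cost_monthly=monitoring_cost_monthly,
        ),
        StrategySpec(kind="rule_based"),
        StrategySpec(kind="fixed", interval_months=2),
        StrategySpec(kind="fixed", interval_months=4),
        StrategySpec(kind="fixed", interval_months=6),
    ]
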