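"""Two-period depression health states.

Depression severity is graded from the PHQ-9 total score (0-27) into three
levels: healthy (H, 0-4), mild (M, 5-9) and moderate-to-severe (S, 10-27).
A Markov state is the *pair* of levels in the previous and current month
(e.g. ``SM`` = severe last month, mild now), which is enough short-term
trajectory to read off treatment response:

* ``HM, MM, HS, MS, SS`` -- non-response or relapse (a treatment change is
  indicated);
* ``HH, MH, SH`` -- remission (score < 5 held for at least one month);
* ``SM`` -- response without remission;
* ``HH, MH`` are *stable* remission, ``SH, SM`` unstable improvement.

Death is handled outside the pair states as a separate absorbing mass in the
cohort engine, since patients may die in any month at any severity.

Structurally, a pair ``(a, b)`` can only be followed by a pair whose first
element is ``b``, so each state has exactly three feasible successors.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from numbers import Real

import numpy as np

__all__ = [
    "SeverityLevel",
    "HealthPairState",
    "ResponseClass",
    "ALL_PAIRS",
    "PAIR_CODES",
    "PAIR_INDEX",
    "NEEDS_CHANGE",
    "REMISSION",
    "RESPONSE_WITHOUT_REMISSION",
    "STABLE",
    "UNSTABLE",
    "NEEDS_CHANGE_MASK",
    "FEASIBLE_MASK",
    "classify_severity",
    "classify_pair",
    "feasible_successors",
]


class SeverityLevel(str, Enum):
    """One of the three PHQ-9 derived severity levels."""

    H = "H"
    M = "M"
    S = "S"

    def __str__(self) -> str:  # serialize as bare letter
        return self.value


#: rank used for ordering levels (H healthiest).
LEVEL_RANK = {SeverityLevel.H: 0, SeverityLevel.M: 1, SeverityLevel.S: 2}


def classify_severity(phq9) -> SeverityLevel:
    """Map a PHQ-9 score to its severity level.

    Scores in [0, 5) are H, [5, 10) are M and [10, 27] are S.  Non-integer
    values are allowed (monthly averaging produces them) and classified by
    the same interval thresholds.

    Raises
    ------
    ValueError
        If ``phq9`` is not a real number in [0, 27].
    """
    if isinstance(phq9, bool) or not isinstance(phq9, Real) or not np.isfinite(phq9):
        raise ValueError(f"PHQ-9 score must be a number in [0, 27], got {phq9!r}")
    x = float(phq9)
    if x < 0.0 or x > 27.0:
        raise ValueError(f"PHQ-9 score must be in [0, 27], got {x!r}")
    if x < 5.0:
        return SeverityLevel.H
    if x < 10.0:
        return SeverityLevel.M
    return SeverityLevel.S


@dataclass(frozen=True)
class HealthPairState:
    """Severity level in month t-1 (``prev``) and month t (``curr``)."""

    prev: SeverityLevel
    curr: SeverityLevel

    @property
    def code(self) -> str:
        return f"{self.prev.value}{self.curr.value}"

    def __str__(self) -> str:
        return self.code

    @classmethod
    def from_code(cls, code: str) -> "HealthPairState":
        if len(code) != 2:
            raise ValueError(f"pair-state code must be two letters, got {code!r}")
        return cls(SeverityLevel(code[0]), SeverityLevel(code[1]))


#: the nine pair states in fixed (row-major over H, M, S) order.
ALL_PAIRS: tuple[HealthPairState, ...] = tuple(
    HealthPairState(a, b) for a in SeverityLevel for b in SeverityLevel
)
PAIR_CODES: tuple[str, ...] = tuple(p.code for p in ALL_PAIRS)
PAIR_INDEX: dict[str, int] = {c: i for i, c in enumerate(PAIR_CODES)}

NEEDS_CHANGE = frozenset(("HM", "MM", "HS", "MS", "SS"))
REMISSION = frozenset(("HH", "MH", "SH"))
RESPONSE_WITHOUT_REMISSION = frozenset(("SM",))
STABLE = frozenset(("HH", "MH"))
UNSTABLE = frozenset(("SH", "SM"))

#: boolean vector over ALL_PAIRS order; True where a treatment change is indicated.
NEEDS_CHANGE_MASK = np.array([c in NEEDS_CHANGE for c in PAIR_CODES])

#: FEASIBLE_MASK[i, j] is True when pair j may follow pair i (j.prev == i.curr).
FEASIBLE_MASK = np.array(
    [[b.prev == a.curr for b in ALL_PAIRS] for a in ALL_PAIRS]
)


@dataclass(frozen=True)
class ResponseClass:
    """Clinical reading of a pair state.

    ``needs_change`` and ``remission`` are mutually exclusive; ``SM`` (response
    without remission) carries neither flag.
    """

    needs_change: bool
    remission: bool
    stable: bool


def classify_pair(state: HealthPairState) -> ResponseClass:
    """Response/remission interpretation of one of the nine pair states."""
    code = state.code
    if code not in PAIR_INDEX:
        raise ValueError(f"unknown pair state {code!r}")
    return ResponseClass(
        needs_change=code in NEEDS_CHANGE,
        remission=code in REMISSION,
        stable=code in STABLE,
    )


def feasible_successors(state: HealthPairState) -> frozenset[HealthPairState]:
    """The three pair states that can structurally follow ``state``."""
    return frozenset(p for p in ALL_PAIRS if p.prev == state.curr)
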