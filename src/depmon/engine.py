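"""Monthly-cycle Markov-cohort engine for depression follow-up strategies.

The cohort is a probability mass over an expanded state

    (pair, treatment line, months-since-change, months-to-next-visit,
     engagement, on-treatment)

plus an absorbing dead mass.  ``pair`` is one of the nine two-period health
states; ``line`` indexes the nine sequential treatment lines plus an
"exhausted" stratum; ``months-since-change`` is capped at 2 and implements
the no-consecutive-changes-within-2-months lockout; the visit countdown is
0..6 months or "none" (adaptive monitoring and disengaged patients);
``on-treatment`` distinguishes patients still taking their current line from
those who discontinued it after an adverse event.

Events within one monthly cycle, in fixed order:

1. background mortality removes a fraction of all alive mass;
2. follow-up attendance is determined (visit countdown reaching zero, or the
   adaptive monthly trigger with the technology's sensitivity/specificity);
3. a per-visit fraction of would-be attendees drops out of follow-up for
   good (they keep background treatment and baseline progression);
4. attending patients in a needs-change state whose lockout has cleared
   advance one treatment line; their transition row is boosted this cycle
   only, moving probability pr_rm to the remission target (curr, H) and
   pr_rsp to the partial-response target (SM; merged into the remission
   target when curr is M);
5. everyone transitions between pair states (baseline group matrix, boosted
   rows for this month's changers);
6. adverse events: patients exactly one month on their line may discontinue
   it (the line is consumed, its cost stops until the next change);
7. counters advance and attendees are rescheduled per the strategy.

Patients who fail all nine lines revert to baseline progression; rule-based
and fixed strategies then book 6-month maintenance visits while adaptive
monitoring keeps its monthly fee with no triggered visits.

A vectorized individual-level microsimulation with the identical event rules
serves as an independent Monte-Carlo oracle for the deterministic engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_prep import RiskGroupProfile
from .model_core import NEEDS_CHANGE_MASK, PAIR_CODES, PAIR_INDEX
from .strategies import (
    POST_EXHAUSTION_INTERVAL,
    RULE_BASED_INTERVALS,
    StrategySpec,
)

__all__ = [
    "ModelParams",
    "TreatmentLine",
    "EngineOptions",
    "CohortState",
    "SimulationResult",
    "default_treatment_lines",
    "per_visit_dropout_probability",
    "boosted_row",
    "init_cohort",
    "step_month",
    "simulate",
    "microsim_oracle",
]

# expanded-state axes: pair, line, since-change, visit countdown, engaged, on-tx
SHAPE = (9, 10, 3, 8, 2, 2)
N_LINES = 9
EXHAUSTED = 9  # line-axis index of the exhausted stratum
V_NONE = 7  # countdown-axis index meaning "no scheduled visit"
LOCKOUT_CLEAR = 2

_NEEDS_IDX = np.flatnonzero(NEEDS_CHANGE_MASK)


@dataclass
class ModelParams:
    horizon_months: int = 24
    monthly_mortality: float = 0.0
    annual_followup_dropout: float = 0.0
    annual_discount_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.horizon_months < 1:
            raise ValueError("horizon_months must be >= 1")
        for f in ("monthly_mortality", "annual_followup_dropout"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{f} must be a probability in [0, 1], got {v}")
        if self.annual_discount_rate < 0:
            raise ValueError("annual_discount_rate must be >= 0")


@dataclass
class TreatmentLine:
    """One of the nine sequential regimens."""

    index: int
    pr_rm: float
    pr_rsp: float
    monthly_cost: float
    adverse_discontinuation: float

    def __post_init__(self) -> None:
        if not (1 <= self.index <= 9):
            raise ValueError("treatment line index must be in 1..9")
        for f in ("pr_rm", "pr_rsp", "adverse_discontinuation"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{f} must be a probability, got {v}")
        if self.pr_rm + self.pr_rsp > 1.0 + 1e-12:
            raise ValueError("pr_rm + pr_rsp must be <= 1")
        if self.monthly_cost < 0:
            raise ValueError("monthly_cost must be >= 0")


def default_treatment_lines() -> list[TreatmentLine]:
    """Nine lines with declining efficacy and rising cost (placeholder values)."""
    pr_rm = [0.35, 0.30, 0.26, 0.22, 0.19, 0.16, 0.13, 0.11, 0.09]
    pr_rsp = [0.20, 0.18, 0.16, 0.14, 0.13, 0.12, 0.11, 0.10, 0.09]
    cost = [25.0, 30.0, 40.0, 55.0, 70.0, 85.0, 100.0, 115.0, 130.0]
    adverse = [0.06, 0.07, 0.08, 0.09, 0.10, 0.11, 0.12, 0.13, 0.14]
    return [
        TreatmentLine(i + 1, pr_rm[i], pr_rsp[i], cost[i], adverse[i])
        for i in range(9)
    ]


@dataclass
class EngineOptions:
    """Knobs the sources leave open; defaults documented in the methods note."""

    visits_per_year_overrides: dict[str, float] = field(default_factory=dict)
    suppress_lockout_visits: bool = False


def nominal_visits_per_year(strategy: StrategySpec) -> float:
    if strategy.kind == "fixed":
        return 12.0 / strategy.interval_months
    if strategy.kind == "rule_based":
        return 3.0  # mean 4-month interval across the 2/4/6 schedule
    return 12.0  # adaptive: monthly assessment cadence


def per_visit_dropout_probability(
    annual_dropout: float, strategy: StrategySpec, options: EngineOptions | None = None
) -> float:
    """Constant-hazard conversion of the annual follow-up dropout to per visit."""
    if annual_dropout <= 0:
        return 0.0
    vpy = (options.visits_per_year_overrides.get(strategy.kind) if options else None)
    if vpy is None:
        vpy = nominal_visits_per_year(strategy)
    return 1.0 - (1.0 - annual_dropout) ** (1.0 / vpy)


@dataclass
class CohortState:
    """Probability mass over the expanded states plus absorbing dead mass."""

    mass: np.ndarray
    dead: float = 0.0

    def total(self) -> float:
        return float(self.mass.sum() + self.dead)

    def alive(self) -> float:
        return float(self.mass.sum())

    def pair_distribution(self) -> np.ndarray:
        return self.mass.sum(axis=(1, 2, 3, 4, 5))


@dataclass
class SimulationResult:
    """Per-cycle bookkeeping needed for economic accrual and audits.

    ``pair_mass`` etc. are cycle-start (post-mortality) quantities; ``attend``
    and ``change`` are the realized attending / treatment-changing masses of
    each cycle; ``snapshots`` are end-of-cycle expanded states.
    """

    strategy: StrategySpec
    pair_mass: np.ndarray  # (horizon, 9)
    alive: np.ndarray  # (horizon,)
    engaged_alive: np.ndarray  # (horizon,)
    tx_line_mass: np.ndarray  # (horizon, 9) on-treatment mass per active line
    exhausted_alive: np.ndarray  # (horizon,)
    attend: np.ndarray  # (horizon,)
    change: np.ndarray  # (horizon,)
    deaths: np.ndarray  # (horizon,)
    snapshots: list[CohortState]
    final_state: CohortState


def _scheduled_countdown(strategy: StrategySpec) -> tuple[np.ndarray, int]:
    """(per-pair initial/reschedule countdown, post-exhaustion countdown)."""
    if strategy.kind == "fixed":
        cnt = np.full(9, strategy.interval_months, dtype=int)
    elif strategy.kind == "rule_based":
        cnt = np.array([RULE_BASED_INTERVALS[c] for c in PAIR_CODES], dtype=int)
    else:
        raise ValueError("adaptive strategy has no scheduled countdown")
    return cnt, POST_EXHAUSTION_INTERVAL


def init_cohort(profile: RiskGroupProfile, strategy: StrategySpec) -> CohortState:
    """All mass on line 1, on treatment, engaged, lockout cleared.

    The first visit is booked per strategy: the fixed interval, the rule-based
    schedule read off the initial pair, or no scheduled visit for adaptive
    monitoring (monthly triggers start immediately).
    """
    d = np.asarray(profile.initial_distribution, dtype=float)
    if abs(d.sum() - 1.0) > 1e-9 or np.any(d < 0):
        raise ValueError("initial distribution must be non-negative and sum to 1")
    mass = np.zeros(SHAPE)
    if strategy.kind == "adaptive":
        mass[:, 0, LOCKOUT_CLEAR, V_NONE, 1, 1] = d
    else:
        cnt, _ = _scheduled_countdown(strategy)
        for p in range(9):
            mass[p, 0, LOCKOUT_CLEAR, cnt[p], 1, 1] = d[p]
    return CohortState(mass=mass, dead=0.0)


def boosted_row(
    pair_idx: int, line: TreatmentLine, baseline_row: np.ndarray
) -> np.ndarray:
    """One-cycle treatment-boost transition row for a needs-change pair.

    ``pr_rm`` of the row's mass is redirected to the remission target
    (curr, H) and ``pr_rsp`` to the response target (curr, M); when curr is M
    the response target coincides with/merges into the remission target MH.
    The remainder follows the baseline row.
    """
    if not NEEDS_CHANGE_MASK[pair_idx]:
        raise ValueError(f"{PAIR_CODES[pair_idx]} is not a needs-change state")
    if line.pr_rm + line.pr_rsp > 1.0 + 1e-12:
        raise ValueError("pr_rm + pr_rsp must be <= 1")
    curr = PAIR_CODES[pair_idx][1]
    row = (1.0 - line.pr_rm - line.pr_rsp) * np.asarray(baseline_row, dtype=float)
    if curr == "S":
        row[PAIR_INDEX["SH"]] += line.pr_rm
        row[PAIR_INDEX["SM"]] += line.pr_rsp
    else:  # curr == "M": improvement target is H either way
        row[PAIR_INDEX["MH"]] += line.pr_rm + line.pr_rsp
    return row


def step_month(
    cohort: CohortState,
    month: int,
    strategy: StrategySpec,
    lines: list[TreatmentLine],
    params: ModelParams,
    profile: RiskGroupProfile,
    options: EngineOptions | None = None,
) -> tuple[CohortState, dict[str, float | np.ndarray]]:
    """Advance the cohort one month; returns the new state and cycle record."""
    if not (1 <= month <= params.horizon_months):
        raise ValueError(f"month {month} outside horizon 1..{params.horizon_months}")
    options = options or EngineOptions()
    P = profile.transition.values
    total_in = cohort.total()
    mass = cohort.mass.copy()
    dead = cohort.dead

    # (1) mortality
    alive_pre = mass.sum()
    deaths = params.monthly_mortality * alive_pre
    dead += deaths
    mass *= 1.0 - params.monthly_mortality

    record = {
        "pair_mass": mass.sum(axis=(1, 2, 3, 4, 5)),
        "alive": float(mass.sum()),
        "engaged_alive": float(mass[:, :, :, :, 1, :].sum()),
        "tx_line_mass": mass[:, :N_LINES, :, :, :, 1].sum(axis=(0, 2, 3, 4)),
        "exhausted_alive": float(mass[:, EXHAUSTED].sum()),
        "deaths": float(deaths),
    }

    # (2) attendance
    if strategy.kind == "adaptive":
        frac = np.zeros(SHAPE)
        need = np.where(NEEDS_CHANGE_MASK, strategy.sensitivity,
                        1.0 - strategy.specificity)
        frac[:, :N_LINES, :, :, 1, :] = need[:, None, None, None, None]
        if options.suppress_lockout_visits:
            for p in _NEEDS_IDX:
                frac[p, :N_LINES, :LOCKOUT_CLEAR, :, 1, :] = 0.0
        att = mass * frac
        stay = mass - att
    else:
        shifted = np.zeros_like(mass)
        shifted[:, :, :, 0:V_NONE - 1] = mass[:, :, :, 1:V_NONE]
        shifted[:, :, :, V_NONE] = mass[:, :, :, V_NONE]
        # countdown 0 is transient: attendees are always rescheduled
        mass = shifted
        att = np.zeros_like(mass)
        att[:, :, :, 0, 1, :] = mass[:, :, :, 0, 1, :]
        stay = mass - att

    # (3) per-visit follow-up dropout
    p_drop = per_visit_dropout_probability(
        params.annual_followup_dropout, strategy, options
    )
    if p_drop > 0:
        dropped = att * p_drop
        att = att - dropped
        dsum = dropped.sum(axis=3)  # collapse countdown
        stay[:, :, :, V_NONE, 0, :] += dsum[:, :, :, 1, :]
    record["attend"] = float(att.sum())

    # (4) treatment change (needs-change pair, lockout cleared, line available)
    changers: list[tuple[int, int, float]] = []  # (pair, new line idx, mass)
    exhaust_flow = np.zeros(9)  # per pair: line-9 failures entering exhaustion
    change_mass = 0.0
    for p in _NEEDS_IDX:
        for l in range(N_LINES):
            m_ch = float(att[p, l, LOCKOUT_CLEAR].sum())
            if m_ch <= 0.0:
                continue
            att[p, l, LOCKOUT_CLEAR] = 0.0
            if l < N_LINES - 1:
                changers.append((p, l + 1, m_ch))
                change_mass += m_ch
            else:
                exhaust_flow[p] += m_ch
    record["change"] = change_mass

    # non-changing attendees are rescheduled (no state change otherwise)
    base_pre = stay
    if strategy.kind == "adaptive":
        base_pre = base_pre + att  # countdown stays "none"
    else:
        cnt, cnt_exh = _scheduled_countdown(strategy)
        for p in range(9):
            base_pre[p, :N_LINES, :, cnt[p], 1, :] += att[p, :N_LINES, :, 0, 1, :]
            base_pre[p, EXHAUSTED, :, cnt_exh, 1, :] += att[p, EXHAUSTED, :, 0, 1, :]
    # line-9 failures enter the exhausted stratum (off treatment, no boost)
    if exhaust_flow.any():
        if strategy.kind == "adaptive":
            v_exh = V_NONE
        else:
            _, v_exh = _scheduled_countdown(strategy)
        for p in np.flatnonzero(exhaust_flow):
            base_pre[p, EXHAUSTED, LOCKOUT_CLEAR, v_exh, 1, 0] += exhaust_flow[p]

    # (5) pair-state transition
    out = np.einsum("ab,a...->b...", P, base_pre)
    for p, new_l, m_ch in changers:
        row = boosted_row(p, lines[new_l], P[p])
        if strategy.kind == "adaptive":
            v_new = V_NONE
        else:
            cnt, _ = _scheduled_countdown(strategy)
            v_new = cnt[p]
        out[:, new_l, 0, v_new, 1, 1] += m_ch * row

    # (6) adverse-event discontinuation, one month after the change
    q = np.array([ln.adverse_discontinuation for ln in lines])
    adverse = out[:, :N_LINES, 1, :, :, 1] * q[None, :, None, None]
    out[:, :N_LINES, 1, :, :, 1] -= adverse
    out[:, :N_LINES, 1, :, :, 0] += adverse

    # (7) months-since-change advances (capped at 2)
    new = np.zeros_like(out)
    new[:, :, 2] = out[:, :, 2] + out[:, :, 1]
    new[:, :, 1] = out[:, :, 0]

    state = CohortState(mass=new, dead=dead)
    if abs(state.total() - total_in) > 1e-10:
        raise AssertionError(
            f"mass not conserved in month {month}: {state.total()} vs {total_in}"
        )
    return state, record


def simulate(
    profile: RiskGroupProfile,
    strategy: StrategySpec,
    lines: list[TreatmentLine],
    params: ModelParams,
    options: EngineOptions | None = None,
) -> SimulationResult:
    """Deterministic cohort simulation over the full horizon."""
    h = params.horizon_months
    state = init_cohort(profile, strategy)
    pair_mass = np.zeros((h, 9))
    alive = np.zeros(h)
    engaged = np.zeros(h)
    tx_line = np.zeros((h, 9))
    exhausted = np.zeros(h)
    attend = np.zeros(h)
    change = np.zeros(h)
    deaths = np.zeros(h)
    snapshots: list[CohortState] = []
    for m in range(1, h + 1):
        state, rec = step_month(state, m, strategy, lines, params, profile, options)
        pair_mass[m - 1] = rec["pair_mass"]
        alive[m - 1] = rec["alive"]
        engaged[m - 1] = rec["engaged_alive"]
        tx_line[m - 1] = rec["tx_line_mass"]
        exhausted[m - 1] = rec["exhausted_alive"]
        attend[m - 1] = rec["attend"]
        change[m - 1] = rec["change"]
        deaths[m - 1] = rec["deaths"]
        snapshots.append(state)
    return SimulationResult(
        strategy=strategy,
        pair_mass=pair_mass,
        alive=alive,
        engaged_alive=engaged,
        tx_line_mass=tx_line,
        exhausted_alive=exhausted,
        attend=attend,
        change=change,
        deaths=deaths,
        snapshots=snapshots,
        final_state=state,
    )


# ---------------------------------------------------------------------------
# individual-level Monte-Carlo oracle


def microsim_oracle(
    profile: RiskGroupProfile,
    strategy: StrategySpec,
    lines: list[TreatmentLine],
    params: ModelParams,
    econ,
    n_individuals: int,
    seed: int,
    options: EngineOptions | None = None,
    return_trajectories: bool = False,
):
    """Individual-level re-implementation of the same event rules.

    Simulates ``n_individuals`` independent patients by explicit random
    sampling and accrues discounted cost and QALYs with the same cycle-start
    conventions as :func:`depmon.economics.accrue`.  Returns
    ``(mean_cost, mean_qaly, se_cost, se_qaly)``; with
    ``return_trajectories=True`` also a dict of event logs for invariant
    checks (per-individual treatment-change months and line sequences).

    ``econ`` is an :class:`depmon.economics.EconomicParams`.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    options = options or EngineOptions()
    rng = np.random.default_rng(seed)
    n = n_individuals
    P = profile.transition.values
    cumP = np.cumsum(P, axis=1)
    h = params.horizon_months

    pair = rng.choice(9, size=n, p=profile.initial_distribution)
    line = np.zeros(n, dtype=int)  # 0..8 active, EXHAUSTED=9
    since = np.full(n, LOCKOUT_CLEAR, dtype=int)
    eng = np.ones(n, dtype=bool)
    ontx = np.ones(n, dtype=bool)
    alive = np.ones(n, dtype=bool)
    if strategy.kind == "adaptive":
        cnt = np.full(n, V_NONE, dtype=int)
    else:
        cnt0, cnt_exh = _scheduled_countdown(strategy)
        cnt = cnt0[pair].copy()

    cost = np.zeros(n)
    qaly = np.zeros(n)
    util = np.array(
        [econ.utility_per_level[PAIR_CODES[p][1]] for p in range(9)]
    )
    line_cost = np.array([ln.monthly_cost for ln in lines])
    avg_line_cost = float(line_cost.mean())
    q_adv = np.array([ln.adverse_discontinuation for ln in lines])
    pr_rm = np.array([ln.pr_rm for ln in lines])
    pr_rsp = np.array([ln.pr_rsp for ln in lines])
    p_drop = per_visit_dropout_probability(
        params.annual_followup_dropout, strategy, options
    )
    monitoring = (
        strategy.monitoring_cost_monthly if strategy.kind == "adaptive" else 0.0
    )
    change_months: list[np.ndarray] = []
    line_log = np.zeros((h + 1, n), dtype=int)
    line_log[0] = line

    for m in range(1, h + 1):
        df = (1.0 + econ.annual_discount_rate) ** (-(m - 1) / 12.0)
        # (1) mortality
        dies = alive & (rng.random(n) < params.monthly_mortality)
        alive &= ~dies
        engaged_now = alive & eng  # pre-dropout, for the monitoring fee
        # (2) attendance
        if strategy.kind == "adaptive":
            needp = np.where(NEEDS_CHANGE_MASK[pair], strategy.sensitivity,
                             1.0 - strategy.specificity)
            attend = engaged_now & (line != EXHAUSTED) & (rng.random(n) < needp)
            if options.suppress_lockout_visits:
                attend &= ~(NEEDS_CHANGE_MASK[pair] & (since < LOCKOUT_CLEAR))
        else:
            due = (cnt > 0) & (cnt != V_NONE)
            cnt = np.where(alive & eng & due, cnt - 1, cnt)
            attend = alive & eng & (cnt == 0)
        pair_at_visit = pair.copy()
        # (3) dropout
        drops = attend & (rng.random(n) < p_drop)
        eng &= ~drops
        cnt[drops] = V_NONE
        attend &= ~drops
        # (4) treatment change
        can_change = (
            attend & NEEDS_CHANGE_MASK[pair] & (since >= LOCKOUT_CLEAR)
        )
        advance = can_change & (line < N_LINES - 1)
        exhaust = can_change & (line == N_LINES - 1)
        # accrual (cycle-start conventions; changers pay the change fee now)
        qaly += np.where(alive, util[pair] / 12.0 * df, 0.0)
        cost += np.where(alive, econ.background_treatment_cost * df, 0.0)
        on_active = alive & ontx & (line != EXHAUSTED)
        cost += np.where(on_active, line_cost[np.minimum(line, 8)] * df, 0.0)
        cost += np.where(alive & (line == EXHAUSTED), avg_line_cost * df, 0.0)
        cost += np.where(attend, econ.followup_visit_cost * df, 0.0)
        cost += np.where(advance, econ.treatment_change_cost * df, 0.0)
        if monitoring:
            cost += np.where(engaged_now, monitoring * df, 0.0)
        # apply the change
        boosted = advance.copy()
        line = np.where(advance, line + 1, line)
        since = np.where(advance, 0, since)
        ontx = np.where(advance, True, ontx)
        line = np.where(exhaust, EXHAUSTED, line)
        ontx = np.where(exhaust, False, ontx)
        change_months.append(np.flatnonzero(advance))
        # (5) transition
        u = rng.random(n)
        rows = cumP[pair]
        if boosted.any():
            idx = np.flatnonzero(boosted)
            brows = np.empty((len(idx), 9))
            for k, i in enumerate(idx):
                brows[k] = boosted_row(pair[i], lines[line[i]], P[pair[i]])
            rows = rows.copy()
            rows[idx] = np.cumsum(brows, axis=1)
        new_pair = np.minimum((u[:, None] > rows).sum(axis=1), 8)
        pair = np.where(alive, new_pair, pair)
        # (6) adverse discontinuation, one month on the line
        at_risk = alive & ontx & (line != EXHAUSTED) & (since == 1)
        adverse = at_risk & (rng.random(n) < q_adv[np.minimum(line, 8)])
        ontx &= ~adverse
        # (7) counters and rescheduling
        since = np.minimum(since + 1, LOCKOUT_CLEAR)
        if strategy.kind != "adaptive":
            # rule-based books from the state observed at the visit (the
            # pre-transition pair); exhausted patients get maintenance visits
            newcnt = np.where(line == EXHAUSTED, cnt_exh, cnt0[pair_at_visit])
            cnt = np.where(attend, newcnt, cnt)
        line_log[m] = line

    mean_cost = float(cost.mean())
    mean_qaly = float(qaly.mean())
    se_cost = float(cost.std(ddof=1) / np.sqrt(n))
    se_qaly = float(qaly.std(ddof=1) / np.sqrt(n))
    if return_trajectories:
        logs = {"change_months": change_months, "line_log": line_log}
        return mean_cost, mean_qaly, se_cost, se_qaly, logs
    return mean_cost, mean_qaly, se_cost, se_qaly
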