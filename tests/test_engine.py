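import numpy as np
import pytest

from depmon.cohort_prep import RiskGroupProfile, TransitionMatrix
from depmon.economics import EconomicParams, accrue
from depmon.engine import (
    EXHAUSTED,
    EngineOptions,
    ModelParams,
    TreatmentLine,
    boosted_row,
    default_treatment_lines,
    init_cohort,
    microsim_oracle,
    per_visit_dropout_probability,
    simulate,
    step_month,
)
from depmon.model_core import ALL_PAIRS, PAIR_CODES, PAIR_INDEX
from depmon.strategies import RULE_BASED_INTERVALS, StrategySpec


def _identity_pattern_matrix() -> TransitionMatrix:
    """Feasible 'stay at (curr, curr)' matrix: (a, b) -> (b, b) w.p. 1."""
    v = np.zeros((9, 9))
    for i, p in enumerate(ALL_PAIRS):
        v[i, PAIR_INDEX[p.curr.value * 2]] = 1.0
    return TransitionMatrix(v)


def _profile(dist=None, matrix=None, name="test") -> RiskGroupProfile:
    d = np.zeros(9)
    if dist is None:
        d[PAIR_INDEX["HH"]] = 1.0
    else:
        for code, w in dist.items():
            d[PAIR_INDEX[code]] = w
    return RiskGroupProfile(
        name=name,
        transition=matrix or _identity_pattern_matrix(),
        initial_distribution=d,
        mean_trajectory=np.zeros(12),
    )


RULE = StrategySpec(kind="rule_based")
FIXED6 = StrategySpec(kind="fixed", interval_months=6)
PERFECT = StrategySpec(
    kind="adaptive", sensitivity=1.0, specificity=1.0, monitoring_cost_monthly=0.0
)


class TestInit:
    def test_all_mass_on_line_one_engaged(self):
        state = init_cohort(_profile(), FIXED6)
        assert state.total() == pytest.approx(1.0)
        assert state.mass[PAIR_INDEX["HH"], 0, 2, 6, 1, 1] == pytest.approx(1.0)

    def test_rule_based_first_visit_matches_schedule_for_every_pair(self):
        for code in PAIR_CODES:
            state = init_cohort(_profile({code: 1.0}), RULE)
            cnt = RULE_BASED_INTERVALS[code]
            assert state.mass[PAIR_INDEX[code], 0, 2, cnt, 1, 1] == pytest.approx(1.0)

    def test_invalid_distribution_rejected(self):
        p = _profile()
        p.initial_distribution = np.full(9, 0.2)  # sums to 1.8
        with pytest.raises(ValueError):
            init_cohort(p, RULE)


class TestStep:
    def test_fixed_point_without_events(self):
        profile = _profile({"HH": 1.0})
        params = ModelParams(horizon_months=5)
        lines = default_treatment_lines()
        state = init_cohort(profile, FIXED6)
        for m in range(1, 5):  # no fixed-6 visit falls in months 1-4
            state, rec = step_month(state, m, FIXED6, lines, params, profile)
            assert rec["attend"] == 0.0
            assert state.pair_distribution()[PAIR_INDEX["HH"]] == pytest.approx(1.0)

    def test_mortality_moves_exact_mass_to_dead(self):
        profile = _profile()
        params = ModelParams(horizon_months=3, monthly_mortality=0.125)
        state = init_cohort(profile, FIXED6)
        state, rec = step_month(state, 1, FIXED6, default_treatment_lines(),
                                params, profile)
        assert state.dead == pytest.approx(0.125)
        assert rec["deaths"] == pytest.approx(0.125)
        state, _ = step_month(state, 2, FIXED6, default_treatment_lines(),
                              params, profile)
        assert state.dead == pytest.approx(0.125 + 0.875 * 0.125)

    def test_month_outside_horizon_rejected(self):
        profile = _profile()
        params = ModelParams(horizon_months=2)
        state = init_cohort(profile, FIXED6)
        with pytest.raises(ValueError):
            step_month(state, 3, FIXED6, default_treatment_lines(), params, profile)


class TestBoost:
    def test_boosted_row_severe_pair(self):
        base = np.zeros(9)
        base[PAIR_INDEX["SS"]] = 1.0
        line = TreatmentLine(2, 0.2, 0.3, 10.0, 0.0)
        row = boosted_row(PAIR_INDEX["SS"], line, base)
        assert row[PAIR_INDEX["SH"]] == pytest.approx(0.2)
        assert row[PAIR_INDEX["SM"]] == pytest.approx(0.3)
        assert row[PAIR_INDEX["SS"]] == pytest.approx(0.5)
        assert row.sum() == pytest.approx(1.0)

    def test_mild_pair_merges_response_into_remission_target(self):
        base = np.zeros(9)
        base[PAIR_INDEX["MM"]] = 1.0
        line = TreatmentLine(2, 0.2, 0.3, 10.0, 0.0)
        row = boosted_row(PAIR_INDEX["MM"], line, base)
        assert row[PAIR_INDEX["MH"]] == pytest.approx(0.5)
        assert row[PAIR_INDEX["MM"]] == pytest.approx(0.5)
        assert row.sum() == pytest.approx(1.0)

    def test_zero_boost_is_identity(self):
        base = np.array([0, 0, 0, 0, 0.6, 0.4, 0, 0, 0.0])
        line = TreatmentLine(1, 0.0, 0.0, 0.0, 0.0)
        row = boosted_row(PAIR_INDEX["MM"], line, base)
        assert np.allclose(row, base)

    def test_non_needs_change_pair_rejected(self):
        with pytest.raises(ValueError):
            boosted_row(PAIR_INDEX["HH"], TreatmentLine(1, 0.1, 0.1, 0, 0),
                        np.full(9, 1 / 9))

    def test_engine_applies_stated_boost_shares(self):
        # whole cohort in SS (p_ss = 1), perfect free monitoring: after the
        # first cycle pr_rm goes to SH and pr_rsp to SM, remainder stays SS
        profile = _profile({"SS": 1.0})
        lines = default_treatment_lines()
        lines[1] = TreatmentLine(2, 0.2, 0.3, 10.0, 0.0)  # the line changed into
        params = ModelParams(horizon_months=2)
        state = init_cohort(profile, PERFECT)
        state, rec = step_month(state, 1, PERFECT, lines, params, profile)
        d = state.pair_distribution()
        assert rec["change"] == pytest.approx(1.0)
        assert d[PAIR_INDEX["SH"]] == pytest.approx(0.2)
        assert d[PAIR_INDEX["SM"]] == pytest.approx(0.3)
        assert d[PAIR_INDEX["SS"]] == pytest.approx(0.5)


class TestSimulate:
    def test_horizon_and_snapshot_count(self, profiles, lines, params, options):
        res = simulate(profiles[0], RULE, lines, params, options)
        assert len(res.snapshots) == 24
        assert res.pair_mass.shape == (24, 9)

    def test_fixed6_attendance_only_on_multiples_of_six(
        self, profiles, lines, params, options
    ):
        res = simulate(profiles[0], FIXED6, lines, params, options)
        for m in range(1, 25):
            if m % 6 == 0:
                assert res.attend[m - 1] > 0
            else:
                assert res.attend[m - 1] == pytest.approx(0.0, abs=1e-15)

    def test_conservation_quick(self, profiles, lines, params, options):
        res = simulate(profiles[1], PERFECT, lines, params, options)
        for snap in res.snapshots:
            assert snap.total() == pytest.approx(1.0, abs=1e-10)

    def test_perfect_adaptive_beats_fixed_schedules_without_dropout(
        self, profiles, lines, econ
    ):
        params = ModelParams(horizon_months=24, monthly_mortality=0.0004,
                             annual_followup_dropout=0.0)
        qalys = {}
        for s in (PERFECT,
                  StrategySpec(kind="fixed", interval_months=2),
                  StrategySpec(kind="fixed", interval_months=4),
                  StrategySpec(kind="fixed", interval_months=6)):
            res = simulate(profiles[0], s, lines, params)
            _, q = accrue(res, s, lines, econ, params)
            qalys[s.label] = q
        for k in ("fixed_2", "fixed_4", "fixed_6"):
            assert qalys["adaptive"] >= qalys[k]


class TestDropoutConversion:
    def test_constant_hazard_conversion(self):
        p = per_visit_dropout_probability(0.2, FIXED6)
        assert p == pytest.approx(1 - (1 - 0.2) ** (1 / 2))
        assert per_visit_dropout_probability(0.0, FIXED6) == 0.0

    def test_override(self):
        opts = EngineOptions(visits_per_year_overrides={"rule_based": 6.0})
        p = per_visit_dropout_probability(0.2, RULE, opts)
        assert p == pytest.approx(1 - 0.8 ** (1 / 6))


class TestMicrosimInvariants:
    def test_lockout_and_line_monotonicity(self, profiles, lines, econ):
        params = ModelParams(horizon_months=24, monthly_mortality=0.0,
                             annual_followup_dropout=0.0)
        out = microsim_oracle(
            profiles[0], PERFECT, lines, params, econ, 3000, seed=17,
            return_trajectories=True,
        )
        _, _, _, _, logs = out
        # no two treatment changes fewer than 2 months apart, per individual
        last_change = {}
        for month_idx, changed in enumerate(logs["change_months"], start=1):
            for ind in changed:
                if ind in last_change:
                    assert month_idx - last_change[ind] >= 2
                last_change[ind] = month_idx
        # treatment line never decreases
        line_log = logs["line_log"]
        assert (np.diff(line_log, axis=0) >= 0).all()

    def test_certain_mortality_kills_everyone_in_month_one(self, profiles, lines, econ):
        params = ModelParams(horizon_months=6, monthly_mortality=1.0)
        cost, qaly, *_ = microsim_oracle(
            profiles[0], RULE, lines, params, econ, 500, seed=3
        )
        assert cost == 0.0 and qaly == 0.0

    def test_reproducible_given_seed(self, profiles, lines, params, econ):
        a = microsim_oracle(profiles[2], RULE, lines, params, econ, 2000, seed=5)
        b = microsim_oracle(profiles[2], RULE, lines, params, econ, 2000, seed=5)
        assert a == b
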