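import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from depmon.economics import (
    CEAResult,
    Dominated,
    EconomicParams,
    accrue,
    classify_vs_comparator,
    discount_factor,
    efficiency_frontier,
    icer,
)
from depmon.engine import ModelParams, simulate
from depmon.strategies import StrategySpec

RULE = StrategySpec(kind="rule_based")


def _res(label, cost, qaly):
    return CEAResult(
        strategy=StrategySpec(kind="rule_based", name=label),
        total_cost=cost,
        total_qaly=qaly,
    )


def brute_force_frontier(results):
    """Independent oracle: a strategy is on the frontier iff no mixture of
    two (possibly identical) other strategies attains at least its QALYs at
    lower cost, or its QALYs at no greater cost with some strict advantage."""
    on = []
    for r in results:
        beaten = False
        for a in results:
            for b in results:
                if a is r or b is r:
                    continue
                lo, hi = sorted((a, b), key=lambda x: x.total_qaly)
                # best mixture cost achieving r's QALYs
                if not (lo.total_qaly <= r.total_qaly <= hi.total_qaly):
                    if a is b and a.total_qaly >= r.total_qaly:
                        mix_cost = a.total_cost
                    else:
                        continue
                elif hi.total_qaly == lo.total_qaly:
                    mix_cost = min(lo.total_cost, hi.total_cost)
                else:
                    w = (r.total_qaly - lo.total_qaly) / (hi.total_qaly - lo.total_qaly)
                    mix_cost = (1 - w) * lo.total_cost + w * hi.total_cost
                if mix_cost < r.total_cost - 1e-12:
                    beaten = True
                    break
            if beaten:
                break
        if not beaten:
            on.append(r)
    return on


class TestDiscount:
    def test_rate_zero_is_one(self):
        assert discount_factor(7, 0.0) == 1.0

    def test_first_cycle_undiscounted(self):
        assert discount_factor(1, 0.03) == 1.0

    def test_one_year_out(self):
        assert discount_factor(13, 0.03) == pytest.approx(1 / 1.03)


class TestAccrue:
    def test_perfect_health_two_years_gives_two_qalys(self, profiles, lines):
        params = ModelParams(horizon_months=24, monthly_mortality=0.0)
        econ = EconomicParams(
            utility_per_level={"H": 1.0, "M": 1.0, "S": 1.0},
            annual_discount_rate=0.0,
        )
        res = simulate(profiles[0], RULE, lines, params)
        _, qaly = accrue(res, RULE, lines, econ, params)
        assert qaly == pytest.approx(2.0)

    def test_certain_death_accrues_nothing(self, profiles, lines, econ):
        params = ModelParams(horizon_months=24, monthly_mortality=1.0)
        res = simulate(profiles[0], RULE, lines, params)
        cost, qaly = accrue(res, RULE, lines, econ, params)
        assert cost == pytest.approx(0.0)
        assert qaly == pytest.approx(0.0)

    def test_cost_linearity(self, profiles, lines, params, econ):
        adaptive = StrategySpec(kind="adaptive", sensitivity=0.8,
                                specificity=0.9, monitoring_cost_monthly=12.0)
        res = simulate(profiles[1], adaptive, lines, params)
        c1, q1 = accrue(res, adaptive, lines, econ, params)
        doubled_lines = [
            type(l)(l.index, l.pr_rm, l.pr_rsp, 2 * l.monthly_cost,
                    l.adverse_discontinuation)
            for l in lines
        ]
        econ2 = EconomicParams(
            utility_per_level=dict(econ.utility_per_level),
            followup_visit_cost=2 * econ.followup_visit_cost,
            background_treatment_cost=2 * econ.background_treatment_cost,
            treatment_change_cost=2 * econ.treatment_change_cost,
            annual_discount_rate=econ.annual_discount_rate,
            wtp_threshold=econ.wtp_threshold,
        )
        adaptive2 = StrategySpec(kind="adaptive", sensitivity=0.8,
                                 specificity=0.9, monitoring_cost_monthly=24.0)
        c2, q2 = accrue(res, adaptive2, doubled_lines, econ2, params)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)
        assert q2 == pytest.approx(q1, rel=1e-12)

    def test_zero_discount_equals_plain_cycle_sums(self, profiles, lines, params):
        econ0 = EconomicParams(annual_discount_rate=0.0)
        res = simulate(profiles[2], RULE, lines, params)
        cost, qaly = accrue(res, RULE, lines, econ0, params)
        util = np.array([econ0.utility_per_level[c[1]] for c in
                         ["HH", "HM", "HS", "MH", "MM", "MS", "SH", "SM", "SS"]])
        line_cost = np.array([l.monthly_cost for l in lines])
        manual_q = float((res.pair_mass @ util).sum() / 12)
        manual_c = float(
            (res.attend * econ0.followup_visit_cost
             + res.alive * econ0.background_treatment_cost
             + res.tx_line_mass @ line_cost
             + res.exhausted_alive * line_cost.mean()).sum()
        )
        assert qaly == pytest.approx(manual_q, rel=1e-12)
        assert cost == pytest.approx(manual_c, rel=1e-12)

    def test_qaly_non_increasing_in_discount_rate(self, profiles, lines, params, econ):
        res = simulate(profiles[0], RULE, lines, params)
        prev = np.inf
        for rate in (0.0, 0.01, 0.03, 0.05, 0.10):
            e = EconomicParams(annual_discount_rate=rate)
            _, q = accrue(res, RULE, lines, e, params)
            assert q <= prev + 1e-12
            prev = q


class TestIcer:
    def test_basic_ratio(self):
        assert icer(_res("b", 200, 1.5), _res("a", 100, 1.0)) == pytest.approx(200.0)

    def test_equal_cost_higher_qaly_is_zero(self):
        assert icer(_res("b", 100, 1.5), _res("a", 100, 1.0)) == 0.0

    def test_no_qaly_gain_signals_dominance(self):
        with pytest.raises(Dominated):
            icer(_res("b", 200, 0.9), _res("a", 100, 1.0))
        with pytest.raises(Dominated):
            icer(_res("b", 200, 1.0), _res("a", 100, 1.0))


class TestFrontier:
    def test_single_strategy(self):
        r = _res("only", 100, 1.0)
        frontier = efficiency_frontier([r])
        assert frontier == [r] and r.icer_vs_next is None

    def test_extended_dominance_example(self):
        a, b, c = _res("A", 100, 1.0), _res("B", 300, 1.1), _res("C", 400, 2.0)
        frontier = efficiency_frontier([a, b, c])
        assert [r.label for r in frontier] == ["A", "C"]
        assert b.dominance == "extended_dominated"
        assert c.icer_vs_next == pytest.approx(300.0)

    def test_strong_dominance(self):
        a, b = _res("A", 100, 1.0), _res("B", 200, 0.5)
        efficiency_frontier([a, b])
        assert b.dominance == "dominated"

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(0)
        rs = [_res(str(i), rng.uniform(0, 1000), rng.uniform(0, 2)) for i in range(6)]
        f1 = {r.label for r in efficiency_frontier(list(rs))}
        f2 = {r.label for r in efficiency_frontier(rs[::-1])}
        assert f1 == f2

    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_brute_force_mixture_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        rs = [_res(str(i), float(rng.uniform(0, 1000)), float(rng.uniform(0, 2)))
              for i in range(n)]
        frontier = efficiency_frontier(list(rs))
        oracle = brute_force_frontier(rs)
        assert {r.label for r in frontier} == {r.label for r in oracle}
        icers = [r.icer_vs_next for r in frontier[1:]]
        assert all(x >= 0 for x in icers)
        assert all(x < y for x, y in zip(icers, icers[1:]))


class TestClassification:
    def test_fewer_qalys_is_dominated_even_if_cheaper(self):
        out = classify_vs_comparator(_res("t", 50, 0.9), _res("r", 100, 1.0), 81630)
        assert out["outcome"] == "dominated" and not out["cost_effective"]

    def test_cost_saving(self):
        out = classify_vs_comparator(_res("t", 50, 1.0), _res("r", 100, 1.0), 81630)
        assert out["outcome"] == "cost_saving" and out["cost_effective"]

    def test_icer_against_wtp(self):
        out = classify_vs_comparator(_res("t", 150_000, 2.0), _res("r", 100_000, 1.0),
                                     81_630)
        assert out["outcome"] == "icer"
        assert out["icer"] == pytest.approx(50_000)
        assert out["cost_effective"]

    def test_equal_qalys_higher_cost_infinite_icer(self):
        out = classify_vs_comparator(_res("t", 200, 1.0), _res("r", 100, 1.0), 81630)
        assert out["outcome"] == "icer"
        assert np.isinf(out["icer"]) and not out["cost_effective"]


class TestEconomicParamsValidation:
    def test_utility_ordering_enforced(self):
        with pytest.raises(ValueError, match="utility"):
            EconomicParams(utility_per_level={"H": 0.5, "M": 0.7, "S": 0.9})

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            EconomicParams(followup_visit_cost=-1.0)
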