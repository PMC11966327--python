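"""Decision tree and Markov cohort engine."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aki_cea import (
    Convention,
    HealthState,
    ModelBundle,
    StratifiedState,
    build_transition_matrix,
    compile_arrays,
    evaluate_strategy,
    run_decision_tree,
    step_markov,
)
from aki_cea.states import STATE_SPACE


def _variant(bundle_dict, **edits):
    data = copy.deepcopy(bundle_dict)
    for path, value in edits.items():
        node = data
        *head, last = path.split("/")
        for key in head:
            node = node[key]
        node[last] = value
    return ModelBundle.model_validate(data)


# ----------------------------------------------------------------------
# decision tree
# ----------------------------------------------------------------------


def test_tree_death_probability_by_total_probability(bundle):
    """P(death at 30 d) = p_aki * P(death|AKI) + (1-p_aki) * P(death|no AKI)."""
    occ, _ = run_decision_tree(
        bundle.strategies["collaborative_surveillance"],
        bundle.transitions,
        bundle.economics,
    )
    p_death = sum(
        v for s, v in occ.items() if s.state is HealthState.DEATH
    )
    expected = 0.079 * 0.091 + 0.921 * (0.014 / 0.999)  # renormalized no-AKI row
    assert p_death == pytest.approx(expected, abs=1e-12)
    assert sum(occ.values()) == pytest.approx(1.0, abs=1e-12)


def test_tree_cost_is_upfront_plus_expected_episode_cost(bundle):
    strat = bundle.strategies["collaborative_surveillance"]
    _, tree_cost = run_decision_tree(strat, bundle.transitions, bundle.economics)
    assert tree_cost == pytest.approx(12.74 + 0.079 * 14000.0)


def test_tree_zero_aki_rate_reduces_to_no_aki_row(bundle, bundle_dict):
    b = _variant(
        bundle_dict,
        **{
            "strategies/assistance/p_aki": {"mean": 0.0, "ci_low": 0.0, "ci_high": 0.0},
        },
    )
    occ, tree_cost = run_decision_tree(
        b.strategies["assistance"], b.transitions, b.economics
    )
    assert tree_cost == pytest.approx(2.69)
    no_aki_row = b.transitions.thirty_day["no_aki"]
    for s, v in occ.items():
        expected = 0.0 if s.aki_history else no_aki_row[s.state].mean
        assert v == pytest.approx(expected, abs=1e-15)


def test_tree_certain_aki_and_certain_death_absorb_everything(bundle_dict):
    row = {
        "NORMAL": {"mean": 0.0}, "CKD": {"mean": 0.0},
        "ESRD": {"mean": 0.0}, "DEATH": {"mean": 1.0},
    }
    b = _variant(
        bundle_dict,
        **{
            "strategies/assistance/p_aki": {"mean": 1.0, "ci_low": 1.0, "ci_high": 1.0},
            "transitions/thirty_day/aki": row,
        },
    )
    occ, tree_cost = run_decision_tree(b.strategies["assistance"], b.transitions, b.economics)
    assert occ[StratifiedState(HealthState.DEATH, True)] == pytest.approx(1.0)
    assert tree_cost == pytest.approx(2.69 + 14000.0)


# ----------------------------------------------------------------------
# Markov stepping
# ----------------------------------------------------------------------


def test_step_with_zero_exits_is_identity(bundle_dict):
    data = copy.deepcopy(bundle_dict)
    for table in data["transitions"]["annual"].values():
        for row in table.values():
            for node in row.values():
                node.update(mean=0.0, ci_low=0.0, ci_high=0.0)
    P = build_transition_matrix(ModelBundle.model_validate(data).transitions)
    occ = np.full(8, 1 / 8)
    assert np.allclose(step_markov(occ, P), occ)


def test_pure_esrd_cohort_single_step(bundle):
    P = build_transition_matrix(bundle.transitions)
    occ = np.zeros(8)
    i = STATE_SPACE.index(StratifiedState(HealthState.ESRD, True))
    occ[i] = 1.0
    out = step_markov(occ, P)
    assert out[i] == pytest.approx(1.0 - 0.345)  # stays ESRD with prob 0.655
    assert out[STATE_SPACE.index(StratifiedState(HealthState.DEATH, True))] == pytest.approx(0.345)


def test_step_rejects_unnormalized_occupancy(bundle):
    P = build_transition_matrix(bundle.transitions)
    with pytest.raises(ValueError, match="sums to"):
        step_markov(np.full(8, 0.2), P)


@settings(deadline=None, max_examples=50)
@given(raw=st.lists(st.floats(0.0, 1.0), min_size=8, max_size=8).filter(lambda v: sum(v) > 0))
def test_step_conserves_probability_mass(bundle, raw):
    P = build_transition_matrix(bundle.transitions)
    occ = np.array(raw) / sum(raw)
    assert step_markov(occ, P).sum() == pytest.approx(1.0, abs=1e-12)


# ----------------------------------------------------------------------
# strategy evaluation
# ----------------------------------------------------------------------


def _degenerate_bundle(bundle_dict, discount_rate):
    """All-normal cohort that never transitions: QALYs reduce to a geometric sum."""
    data = copy.deepcopy(bundle_dict)
    for status in ("aki", "no_aki"):
        data["transitions"]["thirty_day"][status] = {
            "NORMAL": {"mean": 1.0}, "CKD": {"mean": 0.0},
            "ESRD": {"mean": 0.0}, "DEATH": {"mean": 0.0},
        }
    for table in data["transitions"]["annual"].values():
        for row in table.values():
            for node in row.values():
                node.update(mean=0.0, ci_low=0.0, ci_high=0.0)
    data["economics"]["discount_rate"] = discount_rate
    data["economics"]["aki_episode_cost"] = {"mean": 0.0}
    for spec in data["strategies"].values():
        spec["upfront_cost"] = {"mean": 0.0}
    return ModelBundle.model_validate(data)


def test_degenerate_cohort_undiscounted_qalys(bundle_dict):
    b = _degenerate_bundle(bundle_dict, 0.0)
    out = evaluate_strategy(b, "assistance")
    assert out.total_qaly == pytest.approx(0.85 * 3)
    assert out.total_cost == pytest.approx(0.0)


def test_degenerate_cohort_discounted_qalys_match_geometric_sum(bundle_dict):
    b = _degenerate_bundle(bundle_dict, 0.03)
    out = evaluate_strategy(b, "assistance")
    expected = 0.85 * sum(1.03 ** (-t) for t in (1, 2, 3))
    assert out.total_qaly == pytest.approx(expected, rel=1e-12)


def test_trace_conservation_and_monotone_death(bundle):
    for conv in (Convention("pre", False), Convention("post", False), Convention("pre", True)):
        out = evaluate_strategy(bundle, "collaborative_surveillance", conv)
        occ = out.trace.groupby("cycle")["occupancy"].sum()
        assert np.allclose(occ, 1.0, atol=1e-9)
        death = (
            out.trace[out.trace.state == "DEATH"].groupby("cycle")["occupancy"].sum()
        )
        assert (death.diff().dropna() >= -1e-15).all()


def test_cycle_zero_accrues_nothing(bundle):
    out = evaluate_strategy(bundle, "assistance")
    cycle0 = out.trace[out.trace.cycle == 0]
    assert cycle0[["disc_cost", "disc_qaly"]].to_numpy().sum() == 0.0


@pytest.mark.parametrize("parameter,direction", [
    ("annual.after_aki.ESRD.DEATH", "up"),
    ("annual.no_aki.NORMAL.DEATH", "up"),
    ("thirty_day.aki.DEATH", "up"),
])
def test_more_death_means_fewer_qalys(bundle, parameter, direction):
    ref = bundle.parameters()[parameter]
    worse = bundle.with_parameter(parameter, ref.high)
    base_q = evaluate_strategy(bundle, "assistance").total_qaly
    worse_q = evaluate_strategy(worse, "assistance").total_qaly
    assert worse_q <= base_q + 1e-12


def test_more_aki_costs_more_and_yields_less(bundle):
    base = evaluate_strategy(bundle, "assistance")
    worse = bundle.with_parameter("p_aki.assistance", 0.156)
    out = evaluate_strategy(worse, "assistance")
    assert out.total_cost > base.total_cost
    assert out.total_qaly < base.total_qaly


def test_totals_non_increasing_in_discount_rate(bundle, bundle_dict):
    prev_cost, prev_qaly = np.inf, np.inf
    for r in (0.0, 0.03, 0.10):
        data = copy.deepcopy(bundle_dict)
        data["economics"]["discount_rate"] = r
        out = evaluate_strategy(ModelBundle.model_validate(data), "assistance")
        # upfront + episode cost is undiscounted; the discounted tail shrinks
        assert out.total_cost <= prev_cost + 1e-12
        assert out.total_qaly <= prev_qaly + 1e-12
        prev_cost, prev_qaly = out.total_cost, out.total_qaly


def test_accrual_conventions_bracket_each_other(bundle):
    pre = evaluate_strategy(bundle, "assistance", Convention("pre", False))
    post = evaluate_strategy(bundle, "assistance", Convention("post", False))
    half = evaluate_strategy(bundle, "assistance", Convention("pre", True))
    assert min(pre.total_qaly, post.total_qaly) <= half.total_qaly <= max(pre.total_qaly, post.total_qaly)
    assert half.total_qaly == pytest.approx((pre.total_qaly + post.total_qaly) / 2, rel=1e-12)


def test_base_case_regression_values(bundle):
    """Pin the shipped-convention totals so numerical changes are visible."""
    out = evaluate_strategy(bundle, "collaborative_surveillance")
    assert out.total_cost == pytest.approx(2764.442241, abs=1e-4)
    assert out.total_qaly == pytest.approx(2.184841, abs=1e-6)
    arrays = compile_arrays(bundle)
    assert arrays.horizon == 3
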