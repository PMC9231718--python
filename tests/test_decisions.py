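"""Value tables, expected utilities, best actions, regret, sweeps, concordance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aaimpact import (
    ActionSet,
    Scenario,
    ScenarioGrid,
    TherapeuticOutcomeDistribution,
    ValueTable,
    case_bounds_analysis,
    evaluate_actions,
    expected_value,
    regret_profile,
    scenario_sweep,
    stakeholder_concordance,
    value_set_1,
    value_set_2,
)
from aaimpact.inference import BetaParams


def point_mass(j):
    w = [0.0] * 6
    w[j] = 1.0
    return TherapeuticOutcomeDistribution(tuple(w))


def test_point_mass_returns_the_cell_value():
    assert expected_value(value_set_1().row("accept"), point_mass(1)) == 100


@pytest.mark.parametrize(
    "table,action,expected",
    [
        (value_set_1(), "accept", -20.0),
        (value_set_2(), "refuse", -160.0),
        (value_set_2(), "accept", -20.0),
        (value_set_1(), "refuse", 0.0),
    ],
)
def test_expected_value_dot_product(table, action, expected, simple_dist):
    assert expected_value(table.row(action), simple_dist, action) == pytest.approx(expected)


def test_unset_cell_with_positive_probability_is_an_error():
    dist = TherapeuticOutcomeDistribution((0.5, 0.1, 0.1, 0.0, 0.2, 0.1))  # mass on x1
    with pytest.raises(ValueError, match="x1"):
        expected_value(value_set_1().row("accept"), dist, action="accept")


def test_evaluate_actions_tie_and_winner(simple_dist):
    res1 = evaluate_actions(value_set_1(), simple_dist)
    assert res1.values == pytest.approx({"refuse": 0.0, "accept": -20.0, "defer": 0.0})
    assert res1.best == ("refuse", "defer") and res1.tie

    res2 = evaluate_actions(value_set_2(), simple_dist)
    assert res2.best == ("accept",) and not res2.tie


def test_point_mass_reduces_to_column_argmax():
    table = value_set_2()
    res = evaluate_actions(table, point_mass(5))
    best_by_hand = max(table.actions, key=lambda a: table.row(a)[5])
    assert best_by_hand in res.best


def test_regret_profile(simple_dist):
    regrets = regret_profile(value_set_2(), simple_dist)
    assert regrets == pytest.approx({"accept": 0.0, "refuse": 140.0, "defer": 140.0})
    assert min(regrets.values()) == 0.0
    # identical value rows get identical regrets
    assert regrets["refuse"] == regrets["defer"]


def test_identical_rows_always_tie():
    rng = np.random.default_rng(11)
    table = value_set_1()
    for _ in range(25):
        w = rng.dirichlet(np.ones(4))
        dist = TherapeuticOutcomeDistribution((0.0, w[0], w[1], 0.0, w[2], w[3]))
        res = evaluate_actions(table, dist)
        assert ("refuse" in res.best) == ("defer" in res.best)


@settings(deadline=None, max_examples=50)
@given(
    st.lists(st.floats(0.01, 1), min_size=6, max_size=6),
    st.lists(st.floats(-100, 100), min_size=18, max_size=18),
    st.floats(0.1, 10),
    st.floats(-50, 50),
)
def test_affine_equivariance_of_best_actions(raw_w, raw_v, a, b):
    """v -> a*v + b (a>0) maps expected values affinely; best sets are unchanged."""
    w = np.array(raw_w)
    w /= w.sum()
    dist = TherapeuticOutcomeDistribution(tuple(w))
    rows = np.array(raw_v).reshape(3, 6)
    actions = ("refuse", "accept", "defer")
    t1 = ValueTable({act: list(rows[i]) for i, act in enumerate(actions)}, ActionSet(actions))
    t2 = ValueTable(
        {act: list(a * rows[i] + b) for i, act in enumerate(actions)}, ActionSet(actions)
    )
    r1, r2 = evaluate_actions(t1, dist), evaluate_actions(t2, dist)
    assert r1.best == r2.best
    for act in actions:
        assert r2.values[act] == pytest.approx(a * r1.values[act] + b, rel=1e-9, abs=1e-7)


def test_expected_value_against_random_dot_product_oracle():
    """1000 random instances against a plain numpy inner product."""
    rng = np.random.default_rng(3)
    for _ in range(1000):
        w = rng.dirichlet(np.ones(6))
        v = rng.normal(scale=100, size=6)
        dist = TherapeuticOutcomeDistribution(tuple(w))
        got = expected_value(list(v), dist)
        assert got == pytest.approx(float(w @ v), rel=1e-12, abs=1e-9)


def test_scenario_sweep_cells_are_compositional(linkage, structure, tables):
    triple = case_bounds_analysis(BetaParams(16, 44), BetaParams(2, 58), linkage, structure)
    grid = ScenarioGrid(
        (Scenario("s1", 0.4, 0.03), Scenario("s2", 0.1, 0.1))
    )
    out = scenario_sweep(tables, grid, linkage, structure, estimated_cases=triple)
    assert list(out.utilities.index) == ["Expected", "Worst Case", "Best Case", "s1", "s2"]
    for row in out.utilities.index:
        dist = out.distributions[row]
        for (ts, action) in out.utilities.columns:
            cell = out.utilities.loc[row, (ts, action)]
            assert cell == pytest.approx(
                expected_value(tables[ts].row(action), dist, action)
            )
        for ts in tables:
            res = evaluate_actions(tables[ts], dist)
            assert out.best_actions[row][ts] == res.best


def test_scenario_sweep_empty(tables, linkage, structure):
    out = scenario_sweep(tables, ScenarioGrid(()), linkage, structure, estimated_cases=None)
    assert out.utilities.empty


def test_concordance_disagreement_and_trivial_cases(simple_dist, tables):
    rep = stakeholder_concordance(tables, simple_dist)
    assert rep.best_actions["case"]["Value Set 1"] == ("refuse", "defer")
    assert rep.best_actions["case"]["Value Set 2"] == ("accept",)
    assert not rep.agreement["case"].loc["Value Set 1", "Value Set 2"]
    assert rep.concordant == ()

    twins = {"a": value_set_1("a"), "b": value_set_1("b")}
    rep2 = stakeholder_concordance(twins, simple_dist)
    assert rep2.agreement["case"].all().all()
    assert rep2.concordant == ("case",)

    solo = stakeholder_concordance({"only": value_set_2()}, simple_dist)
    assert solo.concordant == ("case",)


def test_concordance_rejects_mismatched_action_sets(simple_dist):
    odd = ValueTable(
        {"go": [0, 1, 1, 0, 0, 0], "stop": [1, 0, 0, 1, 1, 1]}, ActionSet(("go", "stop"))
    )
    with pytest.raises(ValueError, match="action set"):
        stakeholder_concordance({"a": value_set_1(), "b": odd}, simple_dist)


def test_value_table_validation():
    with pytest.raises(ValueError):
        ValueTable({"refuse": [0] * 5, "accept": [0] * 6, "defer": [0] * 6})
    with pytest.raises(ValueError):
        ActionSet(("accept",))
    with pytest.raises(ValueError):
        ActionSet(("a", "a"))
    with pytest.raises(ValueError):
        Scenario("bad", 1.2, 0.5)
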