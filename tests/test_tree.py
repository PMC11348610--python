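"""Decision-tree construction, validation and expected-value rollback."""

from dataclasses import replace
from fractions import Fraction

import pytest

from sptcca import (
    CostParameter,
    DecisionTree,
    ModelInputs,
    Node,
    ProportionParameter,
    RetestStrategy,
    build_spt_tree,
    expected_incremental,
    pathway_outcomes,
    rollback,
    validate_tree,
)
from sptcca.microsim import random_scenario


def _toy_tree(children):
    return DecisionTree(root=Node("decision", "root", children=children))


def test_validate_base_tree_passes(base_inputs):
    assert validate_tree(build_spt_tree(base_inputs)).passed


def test_validate_flags_bad_probability_sum():
    chance = Node(
        "chance",
        "c",
        children=((0.6, Node("terminal", "a", payoff=1.0)), (0.3, Node("terminal", "b", payoff=2.0))),
    )
    report = validate_tree(_toy_tree((chance,)))
    assert any("sum" in v for v in report.violations)


def test_validate_flags_negative_payoff_and_nested_decision():
    bad = Node(
        "chance",
        "c",
        children=(
            (1.0, Node("decision", "nested", children=(Node("terminal", "t", payoff=-1.0),))),
        ),
    )
    report = validate_tree(_toy_tree((bad,)))
    assert any("below the root" in v for v in report.violations)
    assert any("negative payoff" in v for v in report.violations)


def test_rollback_trivial_trees():
    single = _toy_tree((Node("terminal", "only", payoff=42.0),))
    assert rollback(single) == {"only": 42.0}

    split = _toy_tree(
        (
            Node(
                "chance",
                "arm",
                children=(
                    (0.5, Node("terminal", "zero", payoff=0.0)),
                    (0.5, Node("terminal", "ten", payoff=10.0)),
                ),
            ),
        )
    )
    assert rollback(split) == {"arm": 5.0}


def test_rollback_rejects_invalid_tree():
    bad = _toy_tree((Node("chance", "c", children=((0.5, Node("terminal", "t", payoff=1.0)),)),))
    with pytest.raises(ValueError, match="invalid tree"):
        rollback(bad)


def test_manual_arm_ev_matches_closed_form(base_inputs):
    """EV = C + prev * (1 - sens) * (further - 1) * C, by exact fractions."""
    prev = Fraction(1061, 8357)
    sens = Fraction(1485, 2289)
    expected = 39.37 * (1 + float(prev * (1 - sens)))
    evs = rollback(build_spt_tree(base_inputs))
    assert evs["manual"] == pytest.approx(expected, rel=1e-12)


def test_pathway_probabilities_from_exact_fractions(base_inputs):
    prev = Fraction(1061, 8357)
    sens = Fraction(1485, 2289)
    spec = Fraction(9366, 9627)
    expected = {
        "TP": float(prev * sens),
        "FN": float(prev * (1 - sens)),
        "FP": float((1 - prev) * (1 - spec)),
        "TN": float((1 - prev) * spec),
    }
    manual = {o.classification: o.probability for o in pathway_outcomes(base_inputs) if o.strategy == "manual"}
    for cls, value in expected.items():
        assert manual[cls] == pytest.approx(value, rel=1e-12)
    assert sum(manual.values()) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(12))
def test_pathway_probabilities_sum_to_one_random_scenarios(seed):
    for strategy in ("manual", "dspt"):
        outcomes = [o for o in pathway_outcomes(random_scenario(seed)) if o.strategy == strategy]
        assert sum(o.probability for o in outcomes) == pytest.approx(1.0, abs=1e-9)
        payoffs = [o.payoff for o in outcomes]
        evs = rollback(build_spt_tree(random_scenario(seed)))
        assert min(payoffs) - 1e-9 <= evs[strategy] <= max(payoffs) + 1e-9


def test_equal_arms_give_zero_incremental():
    shared_cost = CostParameter("cost", 35.0)
    inputs = ModelInputs(
        prevalence=ProportionParameter("prevalence", 100, 1000),
        manual_sensitivity=ProportionParameter("manual_sensitivity", 80, 100),
        manual_specificity=ProportionParameter("manual_specificity", 95, 100),
        dspt_sensitivity=ProportionParameter("dspt_sensitivity", 80, 100),
        dspt_specificity=ProportionParameter("dspt_specificity", 95, 100),
        manual_cost=replace(shared_cost, label="manual_cost"),
        dspt_cost=replace(shared_cost, label="dspt_cost"),
        further_tests=CostParameter("further_tests", 2.0),
    )
    assert expected_incremental(inputs).incremental == pytest.approx(0.0, abs=1e-12)


def test_zero_prevalence_savings_is_pure_cost_difference(base_inputs):
    inputs = replace(base_inputs, prevalence=ProportionParameter("prevalence", 0, 8357))
    res = expected_incremental(inputs)
    assert res.savings == pytest.approx(39.37 - 30.70, abs=1e-12)


def test_further_tests_of_one_removes_fn_surcharge(base_inputs):
    values = base_inputs.values().with_value("further_tests", 1.0)
    fn = [o for o in pathway_outcomes(values) if o.classification == "FN"]
    assert all(o.payoff == pytest.approx(values.manual_cost if o.strategy == "manual" else values.dspt_cost) for o in fn)


def test_base_case_is_cost_saving(base_inputs):
    res = expected_incremental(base_inputs)
    assert res.incremental < 0
    assert res.savings == pytest.approx(8.5892, abs=1e-3)
    assert res.savings == res.ev_manual - res.ev_dspt


def test_ev_monotone_in_prevalence_and_further_tests(base_values):
    evs = [
        expected_incremental(base_values.with_value("prevalence", p)).ev_manual
        for p in (0.0, 0.1, 0.2, 0.5, 1.0)
    ]
    assert evs == sorted(evs)
    evs = [
        expected_incremental(base_values.with_value("further_tests", f)).ev_manual
        for f in (1.0, 1.5, 2.0, 3.0)
    ]
    assert evs == sorted(evs)


def test_savings_antisymmetric_under_arm_swap(base_inputs):
    inputs = replace(base_inputs, retest_strategy=RetestStrategy.SAME_ARM_RETEST)
    swapped = replace(
        inputs,
        manual_sensitivity=replace(inputs.dspt_sensitivity, label="manual_sensitivity"),
        manual_specificity=replace(inputs.dspt_specificity, label="manual_specificity"),
        dspt_sensitivity=replace(inputs.manual_sensitivity, label="dspt_sensitivity"),
        dspt_specificity=replace(inputs.manual_specificity, label="dspt_specificity"),
        manual_cost=replace(inputs.dspt_cost, label="manual_cost"),
        dspt_cost=replace(inputs.manual_cost, label="dspt_cost"),
    )
    assert expected_incremental(swapped).savings == pytest.approx(
        -expected_incremental(inputs).savings, rel=1e-12
    )


def test_tree_json_round_trips_structure(base_inputs, tmp_path):
    import json

    from sptcca import tree_to_json

    path = tmp_path / "tree.json"
    text = tree_to_json(build_spt_tree(base_inputs), path)
    doc = json.loads(path.read_text())
    assert doc == json.loads(text)
    assert doc["kind"] == "decision"
    assert [c["label"] for c in doc["children"]] == ["manual", "dspt"]
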