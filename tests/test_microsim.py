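"""Patient-level microsimulation oracle and random scenario generator."""

import numpy as np
import pytest

from sptcca import (
    ScenarioValues,
    classification_check,
    expected_incremental,
    random_scenario,
    simulate_cohort,
    simulate_patients,
)
from sptcca.microsim import ArmCohort, CohortResult
from sptcca.params import RetestStrategy


def _values(**overrides):
    defaults = dict(
        prevalence=0.2,
        manual_sensitivity=0.7,
        manual_specificity=0.9,
        dspt_sensitivity=0.6,
        dspt_specificity=0.85,
        manual_cost=40.0,
        dspt_cost=30.0,
        further_tests=2.0,
    )
    defaults.update(overrides)
    return ScenarioValues(**defaults)


def test_all_true_positive_degenerate_case():
    v = _values(prevalence=1.0, manual_sensitivity=1.0, dspt_sensitivity=1.0)
    cohort = simulate_cohort(v, n_patients=500, seed=1)
    assert cohort.manual.counts == {"TP": 500, "FN": 0, "FP": 0, "TN": 0}
    assert cohort.manual.mean_cost == pytest.approx(40.0)
    assert cohort.dspt.mean_cost == pytest.approx(30.0)
    assert cohort.manual.se_cost == pytest.approx(0.0)


def test_all_false_negative_degenerate_case():
    """Everyone sensitized, nothing detected: each patient pays the test plus
    one manual retest."""
    v = _values(prevalence=1.0, manual_sensitivity=0.0, dspt_sensitivity=0.0)
    cohort = simulate_cohort(v, n_patients=400, seed=2)
    assert cohort.manual.counts["FN"] == 400
    assert cohort.manual.mean_cost == pytest.approx(40.0 + 40.0)
    assert cohort.dspt.mean_cost == pytest.approx(30.0 + 40.0)


def test_same_arm_retest_prices_fn_with_own_cost():
    v = _values(
        prevalence=1.0,
        manual_sensitivity=0.0,
        dspt_sensitivity=0.0,
        retest_strategy=RetestStrategy.SAME_ARM_RETEST,
    )
    cohort = simulate_cohort(v, n_patients=300, seed=3)
    assert cohort.dspt.mean_cost == pytest.approx(30.0 + 30.0)


def test_counts_sum_to_cohort_size(base_inputs):
    cohort = simulate_cohort(base_inputs, n_patients=5000, seed=4)
    for arm in (cohort.manual, cohort.dspt):
        assert sum(arm.counts.values()) == 5000


def test_rejects_empty_cohort(base_inputs):
    with pytest.raises(ValueError):
        simulate_cohort(base_inputs, n_patients=0)


def test_cost_distribution_has_at_most_two_support_points(base_inputs):
    records = simulate_patients(base_inputs, n_patients=2000, seed=5)
    for arm, group in records.groupby("arm"):
        assert group["accrued_cost_chf"].nunique() <= 2
        fn = group[group["classification"] == "FN"]
        not_fn = group[group["classification"] != "FN"]
        assert fn["accrued_cost_chf"].nunique() <= 1
        assert not_fn["accrued_cost_chf"].nunique() == 1


def test_base_case_oracle_agreement(base_inputs):
    """Cohort mean cost per arm matches the analytic rollback within 3 SE."""
    cohort = simulate_cohort(base_inputs, n_patients=200_000, seed=6)
    res = expected_incremental(base_inputs)
    assert abs(cohort.manual.mean_cost - res.ev_manual) <= 3 * cohort.manual.se_cost
    assert abs(cohort.dspt.mean_cost - res.ev_dspt) <= 3 * cohort.dspt.se_cost


def test_fn_fraction_converges_to_prevalence_times_miss_rate(base_inputs):
    v = base_inputs.values()
    n = 200_000
    cohort = simulate_cohort(base_inputs, n_patients=n, seed=7)
    expected = v.prevalence * (1 - v.manual_sensitivity)
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(cohort.manual.counts["FN"] / n - expected) <= 3 * se


def test_paired_mode_shares_sensitization_draws(base_inputs):
    cohort = simulate_cohort(base_inputs, n_patients=20_000, seed=8, paired=True)
    manual_sensitized = cohort.manual.counts["TP"] + cohort.manual.counts["FN"]
    dspt_sensitized = cohort.dspt.counts["TP"] + cohort.dspt.counts["FN"]
    assert manual_sensitized == dspt_sensitized


def test_random_scenario_is_valid_and_deterministic():
    for seed in range(10):
        a = random_scenario(seed)
        b = random_scenario(seed)
        assert a == b
        assert a.further_tests.mean >= 1.0
        for p in a.proportion_parameters().values():
            assert 0 < p.count_r < p.sample_n
            assert p.dsa_low <= p.point_estimate <= p.dsa_high
    assert random_scenario(0) != random_scenario(1)


@pytest.mark.parametrize("seed", range(8))
def test_oracle_equivalence_on_random_scenarios(seed):
    inputs = random_scenario(1000 + seed)
    cohort = simulate_cohort(inputs, n_patients=40_000, seed=seed)
    res = expected_incremental(inputs)
    assert abs(cohort.manual.mean_cost - res.ev_manual) <= 3 * cohort.manual.se_cost
    assert abs(cohort.dspt.mean_cost - res.ev_dspt) <= 3 * cohort.dspt.se_cost


def test_classification_check_passes_on_consistent_cohort(base_inputs):
    cohort = simulate_cohort(base_inputs, n_patients=100_000, seed=9)
    check = classification_check(cohort, base_inputs)
    assert check.passed
    assert set(check.statistic) == {"manual", "dspt"}


def test_classification_check_statistic_zero_at_exact_proportions():
    v = _values(prevalence=0.5, manual_sensitivity=0.5, manual_specificity=0.5,
                dspt_sensitivity=0.5, dspt_specificity=0.5)
    arm = lambda name: ArmCohort(name, 1000, 0.0, 0.0, {"TP": 250, "FN": 250, "FP": 250, "TN": 250})
    cohort = CohortResult(1000, arm("manual"), arm("dspt"))
    check = classification_check(cohort, v)
    assert check.statistic["manual"] == pytest.approx(0.0)
    assert check.passed


def test_classification_check_detects_swapped_accuracy(base_inputs):
    from dataclasses import replace

    cohort = simulate_cohort(base_inputs, n_patients=100_000, seed=10)
    swapped = replace(
        base_inputs.values(),
        manual_sensitivity=base_inputs.values().manual_specificity,
        manual_specificity=base_inputs.values().manual_sensitivity,
    )
    check = classification_check(cohort, swapped)
    assert not check.passed


def test_classification_check_rejects_impossible_counts():
    v = _values(prevalence=0.0)
    consistent = simulate_cohort(v, n_patients=1000, seed=11)
    assert classification_check(consistent, v).passed
    impossible = simulate_cohort(_values(prevalence=0.5), n_patients=1000, seed=11)
    with pytest.raises(ValueError, match="zero-probability"):
        classification_check(impossible, v)
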