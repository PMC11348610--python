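"""Patient-level microsimulation: an independent oracle for the tree.

Each simulated patient referred with suspected sensitization is truly
sensitized with probability `prevalence`; the test then comes back positive
with probability `sensitivity` if sensitized, or `1 - specificity` if not.
Every patient accrues one test's cost; a false negative additionally
accrues (further_tests - 1) retests at the applicable retest cost. By the
law of large numbers the per-arm mean cost converges to the decision
tree's rolled-back expected value, which is what the oracle checks.

The two arms are simulated with independent randomness by default (the
model compares population strategies, not paired within-patient results);
``paired=True`` reuses one sensitization draw per patient across arms to
reduce comparison variance.

`random_scenario` generates valid, wide-ranging parameter sets (binomial
proportions, right-skewed positive costs) for property-based testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import (
    CostParameter,
    ModelInputs,
    ProportionParameter,
    RetestStrategy,
    ScenarioValues,
)
from .tree import DSPT, MANUAL, pathway_outcomes

__all__ = [
    "ArmCohort",
    "CohortResult",
    "ClassificationCheck",
    "simulate_cohort",
    "simulate_patients",
    "random_scenario",
    "classification_check",
]

CLASSES = ("TP", "FN", "FP", "TN")


@dataclass(frozen=True)
class ArmCohort:
    """Aggregate microsimulation result for one arm."""

    arm: str
    n_patients: int
    mean_cost: float
    se_cost: float
    counts: dict[str, int]  # TP/FN/FP/TN


@dataclass(frozen=True)
class CohortResult:
    n_patients: int
    manual: ArmCohort
    dspt: ArmCohort

    @property
    def mean_incremental(self) -> float:
        return self.dspt.mean_cost - self.manual.mean_cost


def _retest_cost(values: ScenarioValues, arm: str) -> float:
    if values.retest_strategy is RetestStrategy.MANUAL_RETEST:
        return values.manual_cost
    return values.manual_cost if arm == MANUAL else values.dspt_cost


def _simulate_arm(
    values: ScenarioValues,
    arm: str,
    sensitized: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Returns (classification codes 0..3 for TP/FN/FP/TN, per-patient cost)."""
    n = sensitized.size
    if arm == MANUAL:
        sens, spec, cost = values.manual_sensitivity, values.manual_specificity, values.manual_cost
    else:
        sens, spec, cost = values.dspt_sensitivity, values.dspt_specificity, values.dspt_cost
    u = rng.random(n)
    positive = np.where(sensitized, u < sens, u < (1.0 - spec))
    # 0=TP, 1=FN, 2=FP, 3=TN
    classes = np.where(
        sensitized,
        np.where(positive, 0, 1),
        np.where(positive, 2, 3),
    )
    surcharge = (values.further_tests - 1.0) * _retest_cost(values, arm)
    costs = np.full(n, cost, dtype=float)
    costs[classes == 1] += surcharge
    return classes, costs


def simulate_cohort(
    inputs: ModelInputs | ScenarioValues,
    n_patients: int,
    seed: int = 0,
    paired: bool = False,
) -> CohortResult:
    """Simulate ``n_patients`` referred patients through both arms."""
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    values = inputs.values() if isinstance(inputs, ModelInputs) else inputs
    rng = np.random.default_rng(seed)
    sens_manual = rng.random(n_patients) < values.prevalence
    sens_dspt = sens_manual if paired else rng.random(n_patients) < values.prevalence
    arms = {}
    for arm, sensitized in ((MANUAL, sens_manual), (DSPT, sens_dspt)):
        classes, costs = _simulate_arm(values, arm, sensitized, rng)
        counts = {c: int(np.sum(classes == i)) for i, c in enumerate(CLASSES)}
        se = float(np.std(costs, ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else float("nan")
        arms[arm] = ArmCohort(
            arm=arm,
            n_patients=n_patients,
            mean_cost=float(np.mean(costs)),
            se_cost=se,
            counts=counts,
        )
    return CohortResult(n_patients=n_patients, manual=arms[MANUAL], dspt=arms[DSPT])


def simulate_patients(
    inputs: ModelInputs | ScenarioValues,
    n_patients: int,
    seed: int = 0,
    paired: bool = False,
) -> pd.DataFrame:
    """Patient-level records (one row per patient and arm) for export."""
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    values = inputs.values() if isinstance(inputs, ModelInputs) else inputs
    rng = np.random.default_rng(seed)
    sens_manual = rng.random(n_patients) < values.prevalence
    sens_dspt = sens_manual if paired else rng.random(n_patients) < values.prevalence
    frames = []
    for arm, sensitized in ((MANUAL, sens_manual), (DSPT, sens_dspt)):
        classes, costs = _simulate_arm(values, arm, sensitized, rng)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.arange(n_patients),
                    "arm": arm,
                    "sensitized": sensitized,
                    "test_positive": np.isin(classes, (0, 2)),
                    "classification": np.array(CLASSES)[classes],
                    "accrued_cost_chf": costs,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def random_scenario(seed: int) -> ModelInputs:
    """A valid random parameter set over wide but realistic ranges.

    Proportions keep binomial provenance (1 <= r <= n-1 over samples of
    50-10,000); costs are right-skewed positive (log-normal around the
    tens-of-CHF scale); the further-tests multiplier lies in [1, ~4]; the
    retest strategy is drawn uniformly.
    """
    rng = np.random.default_rng(seed)

    def proportion(label: str, low: float = 0.02, high: float = 0.98) -> ProportionParameter:
        n = int(rng.integers(50, 10_001))
        p = rng.uniform(low, high)
        r = int(np.clip(round(p * n), 1, n - 1))
        point = r / n
        return ProportionParameter(
            label,
            r,
            n,
            dsa_low=max(0.0, point * 0.8),
            dsa_high=min(1.0, point * 1.2),
        )

    def cost(label: str) -> CostParameter:
        mean = float(np.exp(rng.normal(np.log(30.0), 0.5)))
        return CostParameter(label, round(mean, 2))

    further_mean = float(1.0 + rng.gamma(2.0, 0.5))
    strategy = rng.choice([RetestStrategy.MANUAL_RETEST, RetestStrategy.SAME_ARM_RETEST])
    return ModelInputs(
        prevalence=proportion("prevalence", 0.02, 0.6),
        manual_sensitivity=proportion("manual_sensitivity", 0.3, 0.98),
        manual_specificity=proportion("manual_specificity", 0.5, 0.99),
        dspt_sensitivity=proportion("dspt_sensitivity", 0.3, 0.98),
        dspt_specificity=proportion("dspt_specificity", 0.5, 0.99),
        manual_cost=cost("manual_cost"),
        dspt_cost=cost("dspt_cost"),
        further_tests=CostParameter("further_tests", round(further_mean, 3)),
        retest_strategy=strategy,
    )


@dataclass(frozen=True)
class ClassificationCheck:
    """Chi-square goodness of fit of observed TP/FN/FP/TN counts per arm."""

    statistic: dict[str, float]
    p_value: dict[str, float]
    alpha: float

    @property
    def passed(self) -> bool:
        return all(p > self.alpha for p in self.p_value.values())


def classification_check(
    cohort: CohortResult,
    inputs: ModelInputs | ScenarioValues,
    alpha: float = 0.001,
) -> ClassificationCheck:
    """Compare observed classification counts with the tree's pathway
    probabilities; a zero-probability class with a nonzero count is a hard
    failure (the cohort cannot have come from these inputs)."""
    values = inputs.values() if isinstance(inputs, ModelInputs) else inputs
    probs = {
        (o.strategy, o.classification): o.probability for o in pathway_outcomes(values)
    }
    statistic, p_value = {}, {}
    for arm_result in (cohort.manual, cohort.dspt):
        arm = arm_result.arm
        observed = np.array([arm_result.counts[c] for c in CLASSES], dtype=float)
        expected = np.array([probs[(arm, c)] for c in CLASSES]) * arm_result.n_patients
        zero = expected == 0.0
        if np.any(observed[zero] > 0):
            bad = [c for c, z, o in zip(CLASSES, zero, observed) if z and o > 0]
            raise ValueError(f"{arm}: nonzero counts in zero-probability classes {bad}")
        stat, p = stats.chisquare(observed[~zero], expected[~zero])
        if np.sum(~zero) < 2:  # single possible outcome: trivially consistent
            stat, p = 0.0, 1.0
        statistic[arm], p_value[arm] = float(stat), float(p)
    return ClassificationCheck(statistic=statistic, p_value=p_value, alpha=alpha)
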