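"""Model parameters for the skin-prick-test cost-consequence model.

Probability inputs (sensitization prevalence, per-arm sensitivity and
specificity) are defined by a positive count ``r`` out of a sample ``n``;
their point estimate is ``r/n`` and their probabilistic-sensitivity-analysis
distribution is Beta(r, n - r), whose mean equals the point estimate.

Monetary inputs (per-test cost of each arm, and the dimensionless
"further tests" multiplier charged to false negatives) are defined by a
mean and standard deviation; the PSA distribution is a Gamma fitted by the
method of moments. Unless stated otherwise the SD defaults to 20% of the
mean and the deterministic-sensitivity range to mean ± 20%.

All monetary amounts are Swiss francs (CHF) per test at 2023 prices, from
the hospital perspective, over a one-year horizon with no discounting.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "RetestStrategy",
    "ProportionParameter",
    "CostParameter",
    "ArmCostBreakdown",
    "DeviceCostInputs",
    "ModelInputs",
    "ScenarioValues",
    "beta_from_counts",
    "gamma_from_mean_sd",
    "default_sd",
    "straight_line_depreciation",
    "device_cost_per_test",
    "staff_cost_per_test",
    "arm_total",
    "base_case_inputs",
    "base_case_device",
    "manual_arm_breakdown",
    "dspt_arm_breakdown",
    "STAFF_RATE_CHF_PER_MIN",
]

# Per-minute staff rate reproducing the per-test salary costs of CHF 19.96
# (5.5 min, manual read) and CHF 10.89 (3 min, computer-vision read).
STAFF_RATE_CHF_PER_MIN = 19.96 / 5.5

MATERIALS_COST_CHF = 19.41


class RetestStrategy(enum.Enum):
    """How the repeat test after a false negative is costed.

    ``MANUAL_RETEST``: the retest is always a fully manual test (default;
    the repeat referral is read manually regardless of the original arm).
    ``SAME_ARM_RETEST``: the retest uses the same technique as the arm.
    """

    MANUAL_RETEST = "manual_retest"
    SAME_ARM_RETEST = "same_arm_retest"


def beta_from_counts(count_r: int, sample_n: int) -> tuple[float, float, float]:
    """Beta(alpha, beta) and mean for a proportion observed as r positives of n.

    alpha = r and beta = n - r, so the Beta mean is exactly r/n.
    """
    if sample_n <= 0:
        raise ValueError(f"sample_n must be positive, got {sample_n}")
    if count_r < 0 or count_r > sample_n:
        raise ValueError(f"count_r must satisfy 0 <= r <= n, got r={count_r}, n={sample_n}")
    alpha = float(count_r)
    beta = float(sample_n - count_r)
    return alpha, beta, count_r / sample_n


def gamma_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Gamma(shape, scale) with the given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError(f"mean and sd must be positive, got mean={mean}, sd={sd}")
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def default_sd(mean: float) -> float:
    """Default SD: 20% of the mean (the same rule generates ±20% ranges)."""
    if mean < 0:
        raise ValueError(f"mean must be non-negative, got {mean}")
    return 0.20 * mean


def straight_line_depreciation(capital_value: float, useful_life: float) -> float:
    """Annual depreciation: capital spread evenly over its useful life."""
    if useful_life <= 0:
        raise ValueError(f"useful_life must be positive, got {useful_life}")
    if capital_value < 0:
        raise ValueError(f"capital_value must be non-negative, got {capital_value}")
    return capital_value / useful_life


def staff_cost_per_test(minutes: float, rate: float) -> float:
    """Per-test staff cost = reading/recording minutes x CHF-per-minute rate."""
    if minutes < 0 or rate < 0:
        raise ValueError(f"minutes and rate must be non-negative, got {minutes}, {rate}")
    return round(minutes * rate, 2)


@dataclass(frozen=True)
class ProportionParameter:
    """A probability input with binomial provenance (r positives of n).

    The one-way sensitivity range [dsa_low, dsa_high] defaults to the
    degenerate range at the point estimate when not supplied.
    """

    label: str
    count_r: int
    sample_n: int
    dsa_low: float | None = None
    dsa_high: float | None = None

    def __post_init__(self) -> None:
        beta_from_counts(self.count_r, self.sample_n)  # validates counts
        if self.dsa_low is None:
            object.__setattr__(self, "dsa_low", self.point_estimate)
        if self.dsa_high is None:
            object.__setattr__(self, "dsa_high", self.point_estimate)
        if not (0.0 <= self.dsa_low <= self.dsa_high <= 1.0):
            raise ValueError(
                f"{self.label}: DSA range [{self.dsa_low}, {self.dsa_high}] invalid"
            )

    @property
    def point_estimate(self) -> float:
        return self.count_r / self.sample_n

    @property
    def beta_alpha(self) -> float:
        return float(self.count_r)

    @property
    def beta_beta(self) -> float:
        return float(self.sample_n - self.count_r)


@dataclass(frozen=True)
class CostParameter:
    """A monetary input (CHF/test) or dimensionless multiplier with Gamma PSA.

    Omitted ``sd`` defaults to 20% of the mean; an omitted DSA range
    defaults to mean ± 20%.
    """

    label: str
    mean: float
    sd: float | None = None
    dsa_low: float | None = None
    dsa_high: float | None = None

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"{self.label}: mean must be positive, got {self.mean}")
        if self.sd is None:
            object.__setattr__(self, "sd", default_sd(self.mean))
        if self.sd <= 0:
            raise ValueError(f"{self.label}: sd must be positive, got {self.sd}")
        if self.dsa_low is None:
            object.__setattr__(self, "dsa_low", 0.8 * self.mean)
        if self.dsa_high is None:
            object.__setattr__(self, "dsa_high", 1.2 * self.mean)
        if not (0.0 <= self.dsa_low <= self.dsa_high):
            raise ValueError(
                f"{self.label}: DSA range [{self.dsa_low}, {self.dsa_high}] invalid"
            )

    @property
    def gamma_shape(self) -> float:
        return gamma_from_mean_sd(self.mean, self.sd)[0]

    @property
    def gamma_scale(self) -> float:
        return gamma_from_mean_sd(self.mean, self.sd)[1]


@dataclass(frozen=True)
class ArmCostBreakdown:
    """Per-test cost components of one arm.

    ``staff_cost`` is derived as minutes x rate rounded to the centime;
    ``device_per_test`` is zero for the manual arm.
    """

    materials: float
    staff_time: float
    staff_rate: float
    device_per_test: float = 0.0

    def __post_init__(self) -> None:
        for name in ("materials", "staff_time", "staff_rate", "device_per_test"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def staff_cost(self) -> float:
        return staff_cost_per_test(self.staff_time, self.staff_rate)

    @property
    def total(self) -> float:
        return arm_total(self)


def arm_total(breakdown: ArmCostBreakdown) -> float:
    """Total per-test cost: materials + staff + device amortization share."""
    return round(breakdown.materials + breakdown.staff_cost + breakdown.device_per_test, 2)


@dataclass(frozen=True)
class DeviceCostInputs:
    """Capital inputs converting the reader device into a per-test cost."""

    capital_value: float
    useful_life: float
    annual_service: float
    tests_per_year: float

    def __post_init__(self) -> None:
        if self.useful_life <= 0 or self.tests_per_year <= 0:
            raise ValueError("useful_life and tests_per_year must be positive")
        if self.capital_value < 0 or self.annual_service < 0:
            raise ValueError("capital_value and annual_service must be non-negative")


def device_cost_per_test(inputs: DeviceCostInputs) -> float:
    """Annual depreciation plus service fees, spread over annual test volume."""
    annual = straight_line_depreciation(inputs.capital_value, inputs.useful_life)
    return (annual + inputs.annual_service) / inputs.tests_per_year


@dataclass(frozen=True)
class ModelInputs:
    """Complete parameter set for one model evaluation."""

    prevalence: ProportionParameter
    manual_sensitivity: ProportionParameter
    manual_specificity: ProportionParameter
    dspt_sensitivity: ProportionParameter
    dspt_specificity: ProportionParameter
    manual_cost: CostParameter
    dspt_cost: CostParameter
    further_tests: CostParameter
    retest_strategy: RetestStrategy = RetestStrategy.MANUAL_RETEST

    def __post_init__(self) -> None:
        if self.further_tests.mean < 1:
            raise ValueError(
                "further_tests mean must be >= 1 (total tests for a false-negative patient)"
            )

    def proportion_parameters(self) -> dict[str, ProportionParameter]:
        return {
            "prevalence": self.prevalence,
            "manual_sensitivity": self.manual_sensitivity,
            "manual_specificity": self.manual_specificity,
            "dspt_sensitivity": self.dspt_sensitivity,
            "dspt_specificity": self.dspt_specificity,
        }

    def cost_parameters(self) -> dict[str, CostParameter]:
        return {
            "manual_cost": self.manual_cost,
            "dspt_cost": self.dspt_cost,
            "further_tests": self.further_tests,
        }

    def values(self) -> "ScenarioValues":
        """Point-estimate values used by the deterministic tree."""
        return ScenarioValues(
            prevalence=self.prevalence.point_estimate,
            manual_sensitivity=self.manual_sensitivity.point_estimate,
            manual_specificity=self.manual_specificity.point_estimate,
            dspt_sensitivity=self.dspt_sensitivity.point_estimate,
            dspt_specificity=self.dspt_specificity.point_estimate,
            manual_cost=self.manual_cost.mean,
            dspt_cost=self.dspt_cost.mean,
            further_tests=self.further_tests.mean,
            retest_strategy=self.retest_strategy,
        )


# Order in which parameters are sampled / varied; fixed so that PSA seeds
# are portable across runs and exports line up.
PARAMETER_ORDER = (
    "prevalence",
    "manual_sensitivity",
    "manual_specificity",
    "dspt_sensitivity",
    "dspt_specificity",
    "manual_cost",
    "dspt_cost",
    "further_tests",
)


@dataclass(frozen=True)
class ScenarioValues:
    """One concrete numeric scenario (a point estimate set or a PSA draw)."""

    prevalence: float
    manual_sensitivity: float
    manual_specificity: float
    dspt_sensitivity: float
    dspt_specificity: float
    manual_cost: float
    dspt_cost: float
    further_tests: float
    retest_strategy: RetestStrategy = RetestStrategy.MANUAL_RETEST

    def __post_init__(self) -> None:
        for name in (
            "prevalence",
            "manual_sensitivity",
            "manual_specificity",
            "dspt_sensitivity",
            "dspt_specificity",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for name in ("manual_cost", "dspt_cost"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be non-negative and finite, got {v}")
        if self.further_tests < 0 or not math.isfinite(self.further_tests):
            raise ValueError(f"further_tests must be non-negative, got {self.further_tests}")

    def with_value(self, name: str, value: float) -> "ScenarioValues":
        if name not in PARAMETER_ORDER:
            raise KeyError(f"unknown parameter {name!r}")
        return replace(self, **{name: value})


def manual_arm_breakdown() -> ArmCostBreakdown:
    """Cost components of the fully manual arm (5.5 min read, no device)."""
    return ArmCostBreakdown(
        materials=MATERIALS_COST_CHF,
        staff_time=5.5,
        staff_rate=STAFF_RATE_CHF_PER_MIN,
        device_per_test=0.0,
    )


def base_case_device() -> DeviceCostInputs:
    """Reader-device capital figures: CHF 10,400 over 10 years, CHF 1,040/yr
    service, 5,200 tests per year."""
    return DeviceCostInputs(
        capital_value=10_400.0, useful_life=10.0, annual_service=1_040.0, tests_per_year=5_200.0
    )


def dspt_arm_breakdown() -> ArmCostBreakdown:
    """Cost components of the computer-vision arm (3 min read + device share)."""
    return ArmCostBreakdown(
        materials=MATERIALS_COST_CHF,
        staff_time=3.0,
        staff_rate=STAFF_RATE_CHF_PER_MIN,
        device_per_test=round(device_cost_per_test(base_case_device()), 2),
    )


def base_case_inputs(
    retest_strategy: RetestStrategy = RetestStrategy.MANUAL_RETEST,
) -> ModelInputs:
    """The Swiss university-hospital base case.

    Prevalence of grass-pollen sensitization among referred adults is
    1061/8357; manual-arm accuracy is 1485/2289 (sensitivity) and 9366/9627
    (specificity); the computer-vision arm is assumed 2.5 percentage points
    less accurate (1448/2289 and 9132/9627). Per-test costs are CHF 39.37
    (manual) and CHF 30.70 (computer-vision, including CHF 0.40 device
    amortization); a false negative is charged an average of two tests in
    total.
    """
    manual_total = manual_arm_breakdown().total  # 39.37
    dspt_total = dspt_arm_breakdown().total  # 30.70
    return ModelInputs(
        prevalence=ProportionParameter("prevalence", 1061, 8357, 0.10, 0.20),
        manual_sensitivity=ProportionParameter("manual_sensitivity", 1485, 2289, 0.64, 0.66),
        manual_specificity=ProportionParameter("manual_specificity", 9366, 9627, 0.97, 0.98),
        dspt_sensitivity=ProportionParameter("dspt_sensitivity", 1448, 2289, 0.62, 0.64),
        dspt_specificity=ProportionParameter("dspt_specificity", 9132, 9627, 0.94, 0.96),
        manual_cost=CostParameter("manual_cost", manual_total, dsa_low=31.5, dsa_high=47.2),
        dspt_cost=CostParameter("dspt_cost", dspt_total, dsa_low=24.6, dsa_high=36.9),
        further_tests=CostParameter("further_tests", 2.0, dsa_low=1.6, dsa_high=2.4),
        retest_strategy=retest_strategy,
    )
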