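"""Model-specification files and parameter-table export.

A model specification is one YAML (or JSON) document with four blocks:

``proportions``  list of {label, r, n, dsa_low, dsa_high}
``costs``        list of {label, mean, sd?, dsa_low?, dsa_high?}
``device``       {capital, life_years, annual_service, tests_per_year} (optional)
``settings``     {retest_strategy, n_simulations, seed, n_patients}

Omitted cost ``sd``/range fields default to the 20% rule. The proportion
labels must be exactly the five the model uses (prevalence and per-arm
sensitivity/specificity); the cost labels the three (arm costs and the
further-tests multiplier).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .params import (
    CostParameter,
    DeviceCostInputs,
    ModelInputs,
    ProportionParameter,
    RetestStrategy,
)

__all__ = [
    "RunConfig",
    "SchemaError",
    "load_config",
    "save_config",
    "parameter_table",
    "export_parameter_table",
    "base_case_config_path",
]

PROPORTION_LABELS = (
    "prevalence",
    "manual_sensitivity",
    "manual_specificity",
    "dspt_sensitivity",
    "dspt_specificity",
)
COST_LABELS = ("manual_cost", "dspt_cost", "further_tests")


class SchemaError(ValueError):
    """The specification document is missing or misusing a field."""


@dataclass
class RunConfig:
    """Everything a full analysis run needs besides the parameters."""

    config_path: Path | None = None
    output_dir: Path = Path("sptcca_results")
    seed: int = 0
    n_simulations: int = 10_000
    n_patients: int = 100_000
    retest_strategy: RetestStrategy = RetestStrategy.MANUAL_RETEST
    formats: list[str] = field(default_factory=lambda: ["csv", "json", "png"])

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def base_case_config_path() -> Path:
    """Path of the bundled Swiss base-case specification."""
    return Path(resources.files("sptcca").joinpath("data/base_case.yaml"))


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise SchemaError(f"missing required field {key!r} in {where}")
    return mapping[key]


def load_config(path: str | Path) -> tuple[RunConfig, ModelInputs]:
    """Parse and validate a model-specification file."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: document must be a mapping")

    proportions: dict[str, ProportionParameter] = {}
    for item in _require(doc, "proportions", str(path)):
        label = _require(item, "label", "proportions entry")
        proportions[label] = ProportionParameter(
            label=label,
            count_r=int(_require(item, "r", f"proportion {label!r}")),
            sample_n=int(_require(item, "n", f"proportion {label!r}")),
            dsa_low=item.get("dsa_low"),
            dsa_high=item.get("dsa_high"),
        )
    missing = set(PROPORTION_LABELS) - set(proportions)
    if missing:
        raise SchemaError(f"missing proportion parameters: {sorted(missing)}")

    costs: dict[str, CostParameter] = {}
    for item in _require(doc, "costs", str(path)):
        label = _require(item, "label", "costs entry")
        costs[label] = CostParameter(
            label=label,
            mean=float(_require(item, "mean", f"cost {label!r}")),
            sd=item.get("sd"),
            dsa_low=item.get("dsa_low"),
            dsa_high=item.get("dsa_high"),
        )
    missing = set(COST_LABELS) - set(costs)
    if missing:
        raise SchemaError(f"missing cost parameters: {sorted(missing)}")

    settings = doc.get("settings", {}) or {}
    strategy = RetestStrategy(settings.get("retest_strategy", "manual_retest"))

    inputs = ModelInputs(
        **{label: proportions[label] for label in PROPORTION_LABELS},
        **{label: costs[label] for label in COST_LABELS},
        retest_strategy=strategy,
    )
    run = RunConfig(
        config_path=path,
        seed=int(settings.get("seed", 0)),
        n_simulations=int(settings.get("n_simulations", 10_000)),
        n_patients=int(settings.get("n_patients", 100_000)),
        retest_strategy=strategy,
    )
    return run, inputs


def device_from_config(path: str | Path) -> DeviceCostInputs | None:
    """The optional ``device`` block, if the specification carries one."""
    doc = yaml.safe_load(Path(path).read_text())
    block = doc.get("device")
    if block is None:
        return None
    return DeviceCostInputs(
        capital_value=float(_require(block, "capital", "device")),
        useful_life=float(_require(block, "life_years", "device")),
        annual_service=float(_require(block, "annual_service", "device")),
        tests_per_year=float(_require(block, "tests_per_year", "device")),
    )


def save_config(
    inputs: ModelInputs,
    path: str | Path,
    run: RunConfig | None = None,
    device: DeviceCostInputs | None = None,
) -> None:
    """Write a specification file that reloads to an identical ModelInputs."""
    doc: dict = {
        "proportions": [
            {
                "label": p.label,
                "r": p.count_r,
                "n": p.sample_n,
                "dsa_low": p.dsa_low,
                "dsa_high": p.dsa_high,
            }
            for p in inputs.proportion_parameters().values()
        ],
        "costs": [
            {
                "label": c.label,
                "mean": c.mean,
                "sd": c.sd,
                "dsa_low": c.dsa_low,
                "dsa_high": c.dsa_high,
            }
            for c in inputs.cost_parameters().values()
        ],
        "settings": {
            "retest_strategy": inputs.retest_strategy.value,
            "n_simulations": run.n_simulations if run else 10_000,
            "seed": run.seed if run else 0,
            "n_patients": run.n_patients if run else 100_000,
        },
    }
    if device is not None:
        doc["device"] = {
            "capital": device.capital_value,
            "life_years": device.useful_life,
            "annual_service": device.annual_service,
            "tests_per_year": device.tests_per_year,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def parameter_table(inputs: ModelInputs) -> pd.DataFrame:
    """All parameters with point estimates, ranges and PSA distributions."""
    rows = []
    for p in inputs.proportion_parameters().values():
        rows.append(
            {
                "label": p.label,
                "point_estimate": p.point_estimate,
                "dsa_low": p.dsa_low,
                "dsa_high": p.dsa_high,
                "distribution": "Beta",
                "dist_param_1": p.beta_alpha,
                "dist_param_2": p.beta_beta,
                "source": f"counts r={p.count_r}, n={p.sample_n}",
            }
        )
    for c in inputs.cost_parameters().values():
        rows.append(
            {
                "label": c.label,
                "point_estimate": c.mean,
                "dsa_low": c.dsa_low,
                "dsa_high": c.dsa_high,
                "distribution": "Gamma",
                "dist_param_1": c.gamma_shape,
                "dist_param_2": c.gamma_scale,
                "source": f"mean={c.mean}, sd={c.sd}",
            }
        )
    return pd.DataFrame(rows)


def export_parameter_table(inputs: ModelInputs, path: str | Path) -> pd.DataFrame:
    frame = parameter_table(inputs)
    frame.to_csv(path, index=False, float_format="%.6f")
    return frame
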