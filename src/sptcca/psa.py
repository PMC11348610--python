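"""Probabilistic sensitivity analysis by Monte Carlo simulation.

Each draw samples the five probability parameters from their Beta(r, n-r)
distributions and the three cost/multiplier parameters from their
method-of-moments Gamma distributions, all independently, then plugs the
sampled values into the deterministic decision tree and records the
incremental cost (computer-vision minus manual, CHF per test).

Because the incremental cost is multilinear in the independently sampled
parameters, its Monte Carlo mean converges to the deterministic plug-in
value; convergence of the running mean is diagnosed in blocks.

Draw order is fixed (prevalence, manual sensitivity, manual specificity,
computer-vision sensitivity, computer-vision specificity, manual cost,
computer-vision cost, further tests) so a seed fully determines the run.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .params import PARAMETER_ORDER, ModelInputs, ScenarioValues
from .tree import expected_incremental

__all__ = [
    "PSAResult",
    "draw_inputs",
    "run_psa",
    "convergence_trace",
    "distribution_summary",
    "psa_export",
]

_PROPORTIONS = PARAMETER_ORDER[:5]
_COSTS = PARAMETER_ORDER[5:]


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo draws of the incremental cost with summaries.

    ``samples`` holds one row per draw: the eight sampled parameter values
    plus the incremental cost. ``sd`` is NaN for a single draw.
    """

    samples: pd.DataFrame
    seed: int
    n_simulations: int

    @property
    def draws(self) -> np.ndarray:
        return self.samples["incremental_chf"].to_numpy()

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def sd(self) -> float:
        if self.n_simulations < 2:
            return float("nan")
        return float(np.std(self.draws, ddof=1))

    @property
    def percentile_2_5(self) -> float:
        return float(np.percentile(self.draws, 2.5))

    @property
    def percentile_97_5(self) -> float:
        return float(np.percentile(self.draws, 97.5))

    @property
    def prob_cost_saving(self) -> float:
        """Fraction of draws in which the computer-vision arm costs less."""
        return float(np.mean(self.draws < 0.0))

    def summary(self) -> dict:
        return {
            "n_simulations": self.n_simulations,
            "seed": self.seed,
            "mean_incremental_chf": self.mean,
            "sd_incremental_chf": self.sd,
            "percentile_2_5_chf": self.percentile_2_5,
            "percentile_97_5_chf": self.percentile_97_5,
            "prob_cost_saving": self.prob_cost_saving,
            "mean_savings_chf": -self.mean,
        }


def _sample_one(inputs: ModelInputs, rng: np.random.Generator) -> dict[str, float]:
    values: dict[str, float] = {}
    proportions = inputs.proportion_parameters()
    for name in _PROPORTIONS:
        p = proportions[name]
        if p.beta_alpha == 0.0:
            values[name] = 0.0
        elif p.beta_beta == 0.0:
            values[name] = 1.0
        else:
            values[name] = float(rng.beta(p.beta_alpha, p.beta_beta))
    costs = inputs.cost_parameters()
    for name in _COSTS:
        c = costs[name]
        values[name] = float(rng.gamma(c.gamma_shape, c.gamma_scale))
    if values["further_tests"] < 1.0:
        warnings.warn(
            f"sampled further_tests = {values['further_tests']:.4f} < 1; "
            "the false-negative surcharge becomes a rebate for this draw",
            stacklevel=2,
        )
    return values


def draw_inputs(inputs: ModelInputs, rng: np.random.Generator) -> ScenarioValues:
    """One joint parameter draw, point estimates replaced by sampled values."""
    return ScenarioValues(**_sample_one(inputs, rng), retest_strategy=inputs.retest_strategy)


def run_psa(inputs: ModelInputs, n_simulations: int = 10_000, seed: int = 0) -> PSAResult:
    """Sample, re-evaluate the tree per draw, and summarize."""
    if n_simulations < 1:
        raise ValueError(f"n_simulations must be >= 1, got {n_simulations}")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_simulations):
        values = _sample_one(inputs, rng)
        scenario = ScenarioValues(**values, retest_strategy=inputs.retest_strategy)
        values["incremental_chf"] = expected_incremental(scenario).incremental
        rows.append(values)
    samples = pd.DataFrame(rows, columns=[*PARAMETER_ORDER, "incremental_chf"])
    return PSAResult(samples=samples, seed=seed, n_simulations=n_simulations)


def convergence_trace(
    draws: np.ndarray, block: int = 500, tolerance: float = 0.01
) -> int | None:
    """First draw count at which the running mean has stabilised.

    Checkpoints sit at the end of each block of ``block`` draws; the run is
    declared stable at the first checkpoint whose running mean differs from
    the previous checkpoint's (the running mean after the first draw, for
    the first block) by strictly less than ``tolerance`` x |previous|.
    Returns None if the trace never stabilises within the draws given.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("draws must be non-empty")
    if block < 1:
        raise ValueError(f"block must be >= 1, got {block}")
    running = np.cumsum(draws) / np.arange(1, draws.size + 1)
    prev = running[0]
    for end in range(block, draws.size + 1, block):
        current = running[end - 1]
        if abs(current - prev) < tolerance * abs(prev):
            return end
        prev = current
    return None


def distribution_summary(draws: np.ndarray) -> tuple[float, float]:
    """Sample skewness and excess kurtosis of the incremental draws."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 3:
        raise ValueError("need at least 3 draws for shape statistics")
    return float(stats.skew(draws)), float(stats.kurtosis(draws))


def psa_export(
    result: PSAResult,
    out_dir: str | Path,
    stem: str = "psa",
    plots: bool = True,
) -> dict[str, Path]:
    """Write draws CSV, summary JSON and (optionally) diagnostic plots.

    The summary reports both sign conventions: the incremental cost
    (computer-vision minus manual; negative = saving) and the savings
    (manual minus computer-vision; positive = saving).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    draws_path = out_dir / f"{stem}_draws.csv"
    result.samples.to_csv(draws_path, index=False, float_format="%.6f")
    paths["draws"] = draws_path
    summary_path = out_dir / f"{stem}_summary.json"
    summary_path.write_text(json.dumps(result.summary(), indent=2) + "\n")
    paths["summary"] = summary_path
    if plots:
        paths.update(_plots(result, out_dir, stem))
    return paths


def _plots(result: PSAResult, out_dir: Path, stem: str) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    draws = result.draws

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(draws, bins=60, density=True, color="tab:blue", alpha=0.8)
    ax.axvline(0.0, color="black", lw=1)
    ax.set_xlabel("Incremental cost (CHF per test, computer-vision - manual)")
    ax.set_ylabel("Density")
    ax.set_title(f"Monte Carlo incremental cost, n = {result.n_simulations}")
    hist_path = out_dir / f"{stem}_histogram.png"
    fig.tight_layout()
    fig.savefig(hist_path, dpi=150)
    plt.close(fig)
    paths["histogram"] = hist_path

    fig, ax = plt.subplots(figsize=(7, 4))
    running = np.cumsum(draws) / np.arange(1, draws.size + 1)
    ax.plot(np.arange(1, draws.size + 1), running, lw=1)
    ax.set_xlabel("Simulation")
    ax.set_ylabel("Running mean incremental cost (CHF)")
    ax.set_title("Running-mean convergence")
    conv_path = out_dir / f"{stem}_convergence.png"
    fig.tight_layout()
    fig.savefig(conv_path, dpi=150)
    plt.close(fig)
    paths["convergence"] = conv_path
    return paths
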