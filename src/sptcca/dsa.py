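"""One-way deterministic sensitivity analysis (tornado diagram).

Each of the eight model parameters is set to the low and then the high
bound of its plausible range while all others stay at their point
estimates, and the incremental cost (computer-vision minus manual expected
cost per test, CHF) is re-evaluated. Bar width = |incremental(high) -
incremental(low)| orders parameters by influence.

Each parameter enters the model in exactly one place, so varying an arm's
total cost also moves the false-negative retest cost wherever that same
parameter prices the retest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .params import PARAMETER_ORDER, ModelInputs
from .tree import expected_incremental

__all__ = ["TornadoEntry", "one_way_dsa", "rank_by_width", "tornado_export"]


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    incremental_at_low: float
    incremental_at_high: float
    base_incremental: float

    @property
    def bar_width(self) -> float:
        return abs(self.incremental_at_high - self.incremental_at_low)


def _dsa_range(inputs: ModelInputs, name: str) -> tuple[float, float]:
    params = {**inputs.proportion_parameters(), **inputs.cost_parameters()}
    p = params[name]
    if p.dsa_low is None or p.dsa_high is None:  # pragma: no cover - types default these
        raise ValueError(f"parameter {name!r} has no DSA range")
    return p.dsa_low, p.dsa_high


def one_way_dsa(inputs: ModelInputs) -> list[TornadoEntry]:
    """Evaluate the incremental cost at each parameter's range bounds."""
    base_values = inputs.values()
    base = expected_incremental(base_values).incremental
    entries = []
    for name in PARAMETER_ORDER:
        low, high = _dsa_range(inputs, name)
        inc_low = expected_incremental(base_values.with_value(name, low)).incremental
        inc_high = expected_incremental(base_values.with_value(name, high)).incremental
        entries.append(
            TornadoEntry(
                parameter=name,
                low=low,
                high=high,
                incremental_at_low=inc_low,
                incremental_at_high=inc_high,
                base_incremental=base,
            )
        )
    return entries


def rank_by_width(entries: list[TornadoEntry]) -> list[TornadoEntry]:
    """Sort descending by bar width; ties broken alphabetically by label."""
    return sorted(entries, key=lambda e: (-e.bar_width, e.parameter))


def entries_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "incremental_at_low_chf": e.incremental_at_low,
                "incremental_at_high_chf": e.incremental_at_high,
                "width_chf": e.bar_width,
            }
            for e in entries
        ],
        columns=[
            "parameter",
            "low",
            "high",
            "incremental_at_low_chf",
            "incremental_at_high_chf",
            "width_chf",
        ],
    )


def tornado_export(
    entries: list[TornadoEntry],
    csv_path: str | Path,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the ranked tornado table as CSV and, optionally, a bar plot."""
    ranked = rank_by_width(entries)
    frame = entries_frame(ranked)
    frame.to_csv(csv_path, index=False, float_format="%.6f")
    if plot_path is not None and ranked:
        _plot_tornado(ranked, plot_path)
    return frame


def _plot_tornado(ranked: list[TornadoEntry], plot_path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base = ranked[0].base_incremental
    labels = [e.parameter for e in ranked][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(ranked) + 1.5))
    for i, e in enumerate(ranked[::-1]):
        ax.barh(i, e.incremental_at_low - base, left=base, color="tab:blue")
        ax.barh(i, e.incremental_at_high - base, left=base, color="tab:red")
    ax.axvline(base, color="black", lw=1)
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("Incremental cost (CHF per test, computer-vision - manual)")
    ax.set_title("One-way sensitivity of the incremental cost")
    fig.tight_layout()
    fig.savefig(plot_path, dpi=150)
    plt.close(fig)
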