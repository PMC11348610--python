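"""Full result bundle: base case, tornado, PSA, microsimulation check.

`run_all` executes every analysis stage on one parameter set and writes a
directory of CSV/JSON/PNG artefacts plus a machine-readable manifest that
records every input value actually used (guarding against silent
defaulting). All monetary columns are CHF per test; the incremental sign
convention (computer-vision minus manual; negative = saving) is stated in
the column headers and summaries.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from pathlib import Path

from . import __version__
from .config import RunConfig, export_parameter_table, parameter_table
from .dsa import one_way_dsa, tornado_export
from .microsim import classification_check, simulate_cohort
from .params import ModelInputs
from .psa import psa_export, run_psa
from .tree import base_case_report, build_spt_tree, expected_incremental, tree_to_json, validate_tree

logger = logging.getLogger("sptcca")

__all__ = ["run_all"]


def _manifest(config: RunConfig, inputs: ModelInputs) -> dict:
    table = parameter_table(inputs)
    return {
        "package": "sptcca",
        "version": __version__,
        "python": platform.python_version(),
        "config_path": str(config.config_path) if config.config_path else None,
        "seed": config.seed,
        "n_simulations": config.n_simulations,
        "n_patients": config.n_patients,
        "retest_strategy": inputs.retest_strategy.value,
        "parameters": table.to_dict(orient="records"),
    }


def run_all(config: RunConfig, inputs: ModelInputs) -> dict:
    """Run every stage and return a summary dict of headline numbers."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {}

    logger.info("stage=validate")
    tree = build_spt_tree(inputs)
    report = validate_tree(tree)
    if not report.passed:
        raise ValueError("tree validation failed: " + "; ".join(report.violations))
    tree_to_json(tree, out / "tree.json")

    logger.info("stage=parameters")
    export_parameter_table(inputs, out / "parameter_table.csv")

    logger.info("stage=basecase")
    base = expected_incremental(inputs)
    base_case_report(inputs).to_csv(out / "basecase.csv", index=False, float_format="%.6f")
    summary["ev_manual_chf"] = base.ev_manual
    summary["ev_dspt_chf"] = base.ev_dspt
    summary["incremental_chf"] = base.incremental
    summary["savings_chf"] = base.savings

    logger.info("stage=dsa")
    entries = one_way_dsa(inputs)
    plot = out / "tornado.png" if "png" in config.formats else None
    tornado_export(entries, out / "tornado.csv", plot)
    summary["tornado_all_negative"] = all(
        e.incremental_at_low < 0 and e.incremental_at_high < 0 for e in entries
    )

    logger.info("stage=psa seed=%d n=%d", config.seed, config.n_simulations)
    psa_result = run_psa(inputs, n_simulations=config.n_simulations, seed=config.seed)
    psa_export(psa_result, out, plots="png" in config.formats)
    summary["psa_mean_incremental_chf"] = psa_result.mean
    summary["prob_cost_saving"] = psa_result.prob_cost_saving

    logger.info("stage=microsim n_patients=%d", config.n_patients)
    cohort = simulate_cohort(inputs, n_patients=config.n_patients, seed=config.seed)
    check = classification_check(cohort, inputs)
    microsim_report = {
        "n_patients": config.n_patients,
        "seed": config.seed,
        "manual_mean_cost_chf": cohort.manual.mean_cost,
        "manual_se_chf": cohort.manual.se_cost,
        "dspt_mean_cost_chf": cohort.dspt.mean_cost,
        "dspt_se_chf": cohort.dspt.se_cost,
        "analytic_ev_manual_chf": base.ev_manual,
        "analytic_ev_dspt_chf": base.ev_dspt,
        "classification_counts": {
            "manual": cohort.manual.counts,
            "dspt": cohort.dspt.counts,
        },
        "classification_chi2": check.statistic,
        "classification_p": check.p_value,
        "classification_passed": check.passed,
    }
    (out / "microsim_check.json").write_text(json.dumps(microsim_report, indent=2) + "\n")
    summary["microsim_passed"] = check.passed

    manifest = _manifest(config, inputs)
    manifest["elapsed_seconds"] = round(time.time() - t0, 3)
    manifest["summary"] = summary
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("done in %.1fs -> %s", manifest["elapsed_seconds"], out)
    return summary
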