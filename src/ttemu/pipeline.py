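"""End-to-end orchestration: simulate → cohort → exposure → person-months →
weights → estimates → descriptives, from one validated configuration.

Every artifact in the report bundle is stamped with the seed and a hash of
the configuration, and the whole bundle is a plain dict of JSON-serializable
values, so identical configurations give byte-identical serialized reports.
"""

from __future__ import annotations

import hashlib
import json

import pandas as pd

from .cohort import build_cohort
from .config import PipelineConfig
from .datamodel import ClaimsDataset
from .descriptives import baseline_table
from .errors import ConfigurationError
from .estimators import (estimate_itt, estimate_per_protocol, run_sensitivity,
                         subject_table)
from .exposure import BIG, build_timelines
from .persontime import expand_person_months
from .synthetic import generate_population
from .weights import fit_adherence_weights, fit_treatment_weights


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(json.loads(config.model_dump_json()), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig,
                 dataset: ClaimsDataset | None = None) -> dict:
    """Execute the configured stages; return the report bundle.

    If no dataset is supplied, one is generated from ``config.simulation``.
    """
    if dataset is None:
        if config.simulation is None:
            raise ConfigurationError("simulation: no dataset supplied and no simulation block")
        sim = config.simulation.model_copy(update={"seed": config.seed})
        dataset = generate_population(sim)

    cohort, attrition = build_cohort(dataset)
    report: dict = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "n_population": int(len(dataset.patients)),
        "n_cohort": int(len(cohort)),
        "attrition": attrition.to_dict(orient="records"),
    }
    if not len(cohort):
        report["estimates"] = []
        return report

    base = baseline_table(cohort, suppress_below=config.suppress_below)
    report["baseline_table"] = base.fillna("").to_dict(orient="records")

    tw = fit_treatment_weights(cohort, truncation_percentile=config.truncation_pct)
    tw_by_pid = pd.Series(tw.truncated.to_numpy(), index=cohort["patient_id"])
    report["weight_diagnostics"] = {"baseline_treatment": tw.diagnostics()}

    tl = build_timelines(dataset, cohort, gap_days=config.gap_days)
    pm = expand_person_months(cohort, dataset, tl)
    tl60 = build_timelines(dataset, cohort, gap_days=60)
    report["n_deviators_gap30"] = int((tl["deviation_month"] < BIG).sum())
    report["n_deviators_gap60"] = int((tl60["deviation_month"] < BIG).sum())

    estimates = []
    if "itt" in config.analyses:
        subjects = subject_table(cohort, tl, dataset)
        for oc in config.outcomes:
            estimates.append(estimate_itt(subjects, tw.truncated, oc).to_dict())
    pp_selected = [a for a in config.analyses if a.startswith("per_protocol")]
    if "per_protocol" in pp_selected or set(pp_selected) & {"per_protocol_ltfu",
                                                            "per_protocol_gap60"}:
        adh = fit_adherence_weights(pm, truncation_percentile=config.truncation_pct)
        report["weight_diagnostics"]["adherence"] = adh.diagnostics()
        w = adh.truncated * pm["patient_id"].map(tw_by_pid).to_numpy()
        if "per_protocol" in pp_selected:
            for oc in config.outcomes:
                estimates.append(estimate_per_protocol(pm, w, oc).to_dict())
        wanted = set(pp_selected) & {"per_protocol_ltfu", "per_protocol_gap60"}
        if wanted:
            sens = run_sensitivity(dataset, cohort, pm, tw_by_pid,
                                   outcomes=tuple(config.outcomes),
                                   truncation_percentile=config.truncation_pct)
            estimates.extend(e.to_dict() for e in sens if e.analysis in wanted)
    report["estimates"] = estimates
    return report


def emulation_report(report: dict) -> str:
    """Render the report bundle as Markdown (estimates, attrition, weights)."""
    lines = ["# Target-trial emulation report", ""]
    lines.append(f"- seed: {report['seed']}")
    lines.append(f"- config hash: {report['config_hash']}")
    lines.append(f"- population: {report['n_population']}; eligible cohort: "
                 f"{report['n_cohort']}")
    if "n_deviators_gap30" in report:
        lines.append(f"- deviators: {report['n_deviators_gap30']} (30-day gap), "
                     f"{report['n_deviators_gap60']} (60-day gap)")
    lines.append("")
    lines.append("## Attrition flow")
    lines.append("")
    lines.append("| criterion | removed | remaining |")
    lines.append("|---|---|---|")
    for row in report["attrition"]:
        lines.append(f"| {row['criterion']} | {row['removed']} | {row['remaining']} |")
    if report.get("estimates"):
        lines.append("")
        lines.append("## Hazard ratios (initiators vs non-initiators)")
        lines.append("")
        lines.append("| analysis | outcome | HR | 95% CI | events | deviators |")
        lines.append("|---|---|---|---|---|---|")
        for e in report["estimates"]:
            lines.append(
                f"| {e['analysis']} | {e['outcome']} | {e['hazard_ratio']:.3f} | "
                f"{e['ci_lower']:.3f}–{e['ci_upper']:.3f} | {e['n_events']} | "
                f"{e['n_deviators']} |")
    if report.get("weight_diagnostics"):
        lines.append("")
        lines.append("## Weight diagnostics")
        lines.append("")
        for scope, d in report["weight_diagnostics"].items():
            lines.append(f"- {scope}: mean {d['mean']:.4f}, max {d['max']:.3f}, "
                         f"{d['pct_truncated']:.1f}% truncated")
    lines.append("")
    return "\n".join(lines)


def report_json(report: dict) -> str:
    """Deterministic JSON serialization of the report bundle."""
    return json.dumps(report, sort_keys=True, indent=2, default=str)
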