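"""End-to-end orchestration: simulate -> triage -> sweep -> stats -> report.

Every run writes CSV tables plus a JSON manifest (seed, config hash,
package and library versions).  Outputs are a deterministic function of
(config, seed): identical runs produce byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .accounting import scan_savings
from .accuracy import format_sweep, full_sweep
from .cohort import (
    PregnancyRecord,
    apply_eligibility,
    cohort_to_frame,
    read_cohort,
    write_cohort,
)
from .simulate import (
    SyntheticCohortConfig,
    config_from_dict,
    config_to_dict,
    generate_cohort,
    summarize_cohort,
)
from .stats import (
    fisher_exact_two_sided,
    relative_risk,
    suture_preterm_table,
)
from .triage import (
    DerivationConstraints,
    TriageModelSpec,
    derive_triage_model,
    leave_one_hospital_out,
    run_triage,
    triage_cohort,
)


@dataclass
class RunConfig:
    """One pipeline run: exactly one of ``input_path`` (a cohort CSV) or
    ``simulation`` (a synthetic-cohort config) supplies the records."""

    output_dir: Union[str, Path]
    input_path: Optional[Union[str, Path]] = None
    simulation: Optional[SyntheticCohortConfig] = None
    model: TriageModelSpec = field(default_factory=TriageModelSpec)
    derive: bool = False
    constraints: DerivationConstraints = field(default_factory=DerivationConstraints)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("provide exactly one of input_path or simulation")


def _stage(name):
    """Decorator-less stage guard: re-raise with the failing stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a summary dict with the paths written and headline numbers.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("load"):
        if config.simulation is not None:
            sim = config.simulation
            if sim.seed != config.seed:
                from dataclasses import replace as _replace

                sim = _replace(sim, seed=config.seed)
            records = generate_cohort(sim)
            write_cohort(records, out / "cohort.csv")
        else:
            records = read_cohort(config.input_path)

    with _stage("eligibility"):
        eligible, excluded = apply_eligibility(records)

    summary: dict = {
        "n_records": len(records),
        "n_eligible": len(eligible),
        "n_excluded": len(excluded),
    }
    if not eligible:
        (out / "report.json").write_text(
            json.dumps({**summary, "note": "no eligible records"}, indent=2)
        )
        summary["note"] = "no eligible records"
        return summary

    with _stage("summary"):
        summarize_cohort(eligible).to_csv(out / "cohort_summary.csv", index=False)

    with _stage("triage"):
        if config.derive:
            model, derivation = derive_triage_model(eligible, config.constraints)
            (out / "model.yaml").write_text(_model_yaml(model.spec))
            df = cohort_to_frame(eligible)
            if df["hospital"].nunique() >= 2:
                folds = leave_one_hospital_out(df, config.constraints)
                fold_rows = [
                    {k: v for k, v in f.items() if k not in ("model", "derivation")}
                    for f in folds
                ]
                pd.DataFrame(fold_rows).to_csv(out / "validation_folds.csv", index=False)
            summary["derivation"] = derivation
        else:
            model = config.model
        outcomes_df = triage_cohort(eligible, model)
        outcomes_df.to_csv(out / "triage_outcomes.csv", index=False)

    with _stage("accounting"):
        acc = scan_savings([run_triage(r, model) for r in eligible])
        summary["scan_accounting"] = {
            "n_total": acc.n_total,
            "n_exit_after_1": acc.n_exit_after_1,
            "n_exit_after_2": acc.n_exit_after_2,
            "n_complete_3": acc.n_complete_3,
            "scans_performed": acc.scans_performed,
            "scans_avoided": acc.scans_avoided,
            "scheduled_followups": acc.scheduled_followups,
            "pct_followups_avoided": round(acc.pct_followups_avoided, 2),
        }

    with _stage("sweep"):
        sweep = full_sweep(eligible)
        sweep.to_csv(out / "sweep.csv", index=False)
        format_sweep(sweep).to_csv(out / "sweep_formatted.csv", index=False)

    with _stage("stats"):
        stats_block = {}
        try:
            t = suture_preterm_table(eligible, outcome="preterm")
            if t.a + t.b > 0 and t.c + t.d > 0:
                rr_term = relative_risk(suture_preterm_table(eligible, "term").swap_rows())
                stats_block = {
                    "preterm_monofilament": f"{t.a}/{t.a + t.b}",
                    "preterm_braided": f"{t.c}/{t.c + t.d}",
                    "fisher_p": fisher_exact_two_sided(t),
                    "term_rr_braided_vs_mono": rr_term.rr,
                    "term_rr_ci": [rr_term.ci_low, rr_term.ci_high],
                }
        except ValueError:
            stats_block = {"note": "no cerclage recipients; suture stats skipped"}
        summary["suture_stats"] = _json_safe(stats_block)

    with _stage("manifest"):
        manifest = {
            "cltriage_version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "mode": "derive" if config.derive else "apply",
            "input": str(config.input_path) if config.input_path else None,
            "simulation": config_to_dict(config.simulation)
            if config.simulation is not None else None,
            "model": config.model.to_dict(),
        }
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True, default=str).encode()
        ).hexdigest()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        (out / "report.json").write_text(
            json.dumps(_json_safe(summary), indent=2, default=str)
        )

    return summary


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    return obj


def _model_yaml(spec: TriageModelSpec) -> str:
    import yaml

    return yaml.safe_dump(spec.to_dict(), sort_keys=True)


def load_model_yaml(path) -> TriageModelSpec:
    import yaml

    with open(path) as fh:
        return TriageModelSpec.from_dict(yaml.safe_load(fh))


def load_simulation_yaml(path) -> SyntheticCohortConfig:
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
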