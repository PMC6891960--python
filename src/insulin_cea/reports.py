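"""Report writers: per-group result tables, calibration output, CEAC files.

Each top-level writer produces CSV and/or JSON under an output directory and
finishes by writing a ``manifest.json`` (:class:`RunManifest`) listing every
file produced, so a run's outputs are self-describing.  Reruns with identical
inputs and seeds produce byte-identical primary outputs.  Monetary values are
carried at full precision internally and rounded to 2 decimals only here, at
the report boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import metadata
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .calibration import CalibrationReport, calibrate, write_calibrated_configs
from .model import Arm, ArmOutcome, ComparisonResult, evaluate
from .parameters import ModelParameters
from .psa import PsaResult

__all__ = [
    "RunManifest",
    "evaluation_table",
    "write_evaluation_report",
    "write_calibration_report",
    "write_scenario_table",
    "write_ceac",
]

log = logging.getLogger("insulin_cea")


def _version() -> str:
    try:
        return metadata.version("insulin-cea")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunManifest:
    """Record of one report-producing run; written last, lists every output."""

    command: str
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None
    outputs: list[str] = field(default_factory=list)

    def add(self, path: Path) -> Path:
        self.outputs.append(str(path))
        return path

    def write(self, outdir: Path) -> Path:
        payload = {
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "artifact_version": _version(),
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "outputs": sorted(self.outputs),
        }
        path = Path(outdir) / "manifest.json"
        path.write_text(json.dumps(payload, indent=2))
        return path


def evaluation_table(
    deg: ArmOutcome, gla: ArmOutcome, result: ComparisonResult
) -> pd.DataFrame:
    """Per-arm cost breakdown with increments, one row per cost/outcome line."""
    rows = []
    for name, attr in [
        ("insulin", "insulin_cost"),
        ("hypoglycaemia_total", "hypo_cost_total"),
        ("nonsevere_daytime", "hypo_cost_daytime"),
        ("nonsevere_nocturnal", "hypo_cost_nocturnal"),
        ("severe", "hypo_cost_severe"),
        ("total_costs", "total_cost"),
    ]:
        d, g = getattr(deg, attr), getattr(gla, attr)
        rows.append({"row": name, "degludec": round(d, 2), "glargine": round(g, 2), "incremental": round(d - g, 2)})
    rows.append(
        {
            "row": "qalys",
            "degludec": round(deg.qalys, 4),
            "glargine": round(gla.qalys, 4),
            "incremental": round(result.delta_qalys, 4),
        }
    )
    rows.append(
        {
            "row": "icer",
            "degludec": None,
            "glargine": None,
            "incremental": None if result.icer is None else round(result.icer, 2),
        }
    )
    return pd.DataFrame(rows)


def write_evaluation_report(params: ModelParameters, outdir: Path) -> pd.DataFrame:
    """Evaluate one group and write the result table as CSV + JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command="evaluate", config={"group": params.group.value})
    log.info("evaluating %s over %.3g-year horizon", params.group.value, params.horizon_years)
    deg, gla, result = evaluate(params)
    table = evaluation_table(deg, gla, result)
    stem = f"evaluation_{params.group.value}"
    table.to_csv(manifest.add(outdir / f"{stem}.csv"), index=False)
    payload = {
        "group": params.group.value,
        "delta_cost": result.delta_cost,
        "delta_qalys": result.delta_qalys,
        "icer": result.icer,
        "dominance": result.dominance.value,
        "table": table.to_dict(orient="records"),
    }
    manifest.add(outdir / f"{stem}.json").write_text(json.dumps(payload, indent=2))
    manifest.write(outdir)
    return table


def write_calibration_report(
    outdir: Path, report: Optional[CalibrationReport] = None
) -> CalibrationReport:
    """Write solved parameters, the residual table and per-group config files.

    Raises ``RuntimeError`` if any reproduced cell misses its tolerance, after
    writing the evidence.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = report if report is not None else calibrate()
    manifest = RunManifest(command="calibrate")
    manifest.add(outdir / "calibration_report.json").write_text(
        json.dumps(report.to_dict(), indent=2)
    )
    residuals = pd.DataFrame(
        [{"cell": k, "relative_error": v} for k, v in sorted(report.residuals.items())]
    )
    residuals.to_csv(manifest.add(outdir / "calibration_residuals.csv"), index=False)
    for path in write_calibrated_configs(outdir / "configs", report):
        manifest.add(path)
    manifest.write(outdir)
    log.info("calibration max residual %.4e (ok=%s)", report.max_residual, report.ok)
    if not report.ok:
        raise RuntimeError(f"calibration failed: {report.failures}")
    return report


def write_scenario_table(table: pd.DataFrame, outdir: Path, name: str = "scenarios") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command=name)
    out = table.copy()
    for col in ("delta_cost", "icer"):
        if col in out:
            out[col] = out[col].round(2)
    if "delta_qalys" in out:
        out["delta_qalys"] = out["delta_qalys"].round(4)
    path = manifest.add(outdir / f"{name}.csv")
    out.to_csv(path, index=False)
    manifest.write(outdir)
    return path


def write_ceac(result: PsaResult, group_label: str, outdir: Path) -> Path:
    """CEAC as (wtp, probability) CSV plus a summary JSON for one group."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command="psa", seed=result.seed, config={"group": group_label, "n": result.n})
    path = manifest.add(outdir / f"ceac_{group_label}.csv")
    pd.DataFrame(result.ceac, columns=["wtp", "probability_cost_effective"]).to_csv(
        path, index=False
    )
    summary = {
        "group": group_label,
        "n": result.n,
        "seed": result.seed,
        "wtp_threshold": result.wtp_threshold,
        "probability_cost_effective_at_threshold": result.prob_cost_effective_at_threshold,
        "mean_delta_cost": result.mean_delta_cost,
        "mean_delta_qalys": result.mean_delta_qalys,
        "icer_of_means": result.icer_of_means,
        "mean_nmb_at_threshold": result.mean_nmb_at_threshold,
    }
    manifest.add(outdir / f"psa_summary_{group_label}.json").write_text(
        json.dumps(summary, indent=2)
    )
    manifest.write(outdir)
    return path
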