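"""Report writers and run manifests."""
from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .parameters import ModelParameters, registry_frame, serialize_parameters
from .pipeline import ModelRun, run_model
from .sensitivity import one_way_sa, tornado_frame

FLOAT_FMT = "%.12g"   # 12 significant digits for lossless-enough round-trips


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def write_manifest(out_dir: Path, params: ModelParameters, seed: int | None,
                   files: list[Path]) -> Path:
    config_text = serialize_parameters(params)
    manifest = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": seed,
        "software_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": [f.name for f in files],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def cost_report_frame(run: ModelRun) -> pd.DataFrame:
    """(arm, year, component, undiscounted, discounted, pppm) rows matching
    the savings decomposition (medication vs inpatient contributions)."""
    frames = []
    for arm, bd in run.costs.items():
        df = bd.to_frame()
        df["pppm"] = df["undiscounted"] / 12.0
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_base_case(params: ModelParameters, out_dir, seed: int | None = None,
                  wtp_grid=None) -> dict[str, Path]:
    """Write the base-case report set: cost breakdown, PPPM table, CEA JSON,
    threshold curve, parameter registry, and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = run_model(params)
    d = params.disease.key
    files = {
        "costs": _write_csv(cost_report_frame(run), out / f"{d}_cost_breakdown.csv"),
        "pppm": _write_csv(run.pppm_frame(), out / f"{d}_pppm_savings.csv"),
        "threshold": _write_csv(run.threshold_frame(wtp_grid), out / f"{d}_threshold_curve.csv"),
        "registry": _write_csv(registry_frame(params), out / f"{d}_parameter_registry.csv"),
    }
    cea = {
        "disease": d,
        "delta_cost_savings": run.cea.delta_cost_savings,
        "delta_qaly": run.cea.delta_qaly,
        "pppm_by_year": [float(x) for x in run.pppm],
        "pppm_3yr_average": run.pppm_average,
        "breakeven_at_50k": run.cea.breakeven(50_000.0),
        "breakeven_at_100k": run.cea.breakeven(100_000.0),
    }
    cea_path = out / f"{d}_cea.json"
    cea_path.write_text(json.dumps(cea, indent=2))
    files["cea"] = cea_path
    files["manifest"] = write_manifest(out, params, seed, list(files.values()))
    return files


def run_sa(params: ModelParameters, outcome: str, out_dir,
           parameter_list=None, seed: int | None = None) -> Path:
    """Write a tornado-ordered one-way sensitivity report for one outcome."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = one_way_sa(params, outcome, parameter_list)
    if not results:
        import warnings

        warnings.warn("empty parameter list: writing an empty tornado report")
        df = pd.DataFrame(columns=["rank", "parameter", "low", "high",
                                   "outcome_low", "outcome_high", "base_outcome", "span"])
    else:
        df = tornado_frame(results)
    path = _write_csv(df, out / f"{params.disease.key}_tornado_{outcome}.csv")
    write_manifest(out, params, seed, [path])
    return path


def summary_text(run: ModelRun) -> str:
    """Human-oriented summary (whole dollars; machine files keep precision)."""
    d = run.params.disease
    lines = [f"{d.label} ({d.biomarker}, {d.units}) - DTx + TAU vs TAU alone",
             "HRU savings per participant per month (year-1 dollars):"]
    for y in (1, 2, 3):
        lines.append(f"  year {y}: ${run.pppm[y - 1]:,.0f}")
    lines.append(f"  3-year average: ${run.pppm_average:,.0f}")
    lines.append(f"Discounted 3-year HRU savings per enrollee: ${run.cea.delta_cost_savings:,.0f}")
    lines.append(f"Incremental QALYs per enrollee: {run.cea.delta_qaly:.4f}")
    for wtp in (50_000, 100_000):
        lines.append(f"Break-even 3-year program cost at ${wtp // 1000}k/QALY: "
                     f"${run.cea.breakeven(wtp):,.0f}")
    return "\n".join(lines)
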