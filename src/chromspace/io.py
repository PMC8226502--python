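"""File formats: run-table CSV, model JSON, map/robustness CSV, config YAML.

All user-facing files use %B (percent) for mobile-phase composition; the
package converts to fractions at this boundary.  Report CSVs round
retention times and resolutions to 2 decimals; model JSON keeps full
precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml
from pydantic import ValidationError

from .calibration import (
    RUN_TABLE_COLUMNS,
    CalibrationDesign,
    FittedModel,
    RunTable,
)
from .chromatogram import Chromatogram
from .config import ProjectConfig
from .design_space import DesignSpaceMap, WorkingPoint
from .errors import InputError, ParseError
from .lss import SoluteLSS
from .robustness import RobustnessResult

__all__ = [
    "read_run_table",
    "write_run_table",
    "model_to_json",
    "model_from_json",
    "write_chromatogram_csv",
    "write_map_csv",
    "write_robustness_csv",
    "write_working_point_json",
    "load_config",
]

PathLike = Union[str, Path]


def read_run_table(path: PathLike) -> RunTable:
    """Parse a run-table CSV (UTF-8, '.' decimal separator).

    Header: run_id,tG_min,T_C,pH,flow_mL_min,pctB_start,pctB_end,
    compound_id,tR_min.  A blank tR cell marks an absent (e.g. degraded)
    peak.  Malformed headers or non-numeric cells raise a ParseError with
    the offending line number.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        required = [c for c in RUN_TABLE_COLUMNS]
        if header[: len(required)] != required:
            raise ParseError(
                f"{path}:1: bad header {header!r}, expected {required!r}"
            )
        rows = []
        numeric = {"tG_min", "T_C", "pH", "flow_mL_min", "pctB_start", "pctB_end"}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(",")
            if len(cells) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} cells, got {len(cells)}"
                )
            row = dict(zip(header, cells))
            parsed = {}
            for col in header:
                val = row[col].strip()
                if col in ("run_id", "compound_id"):
                    parsed[col] = val
                elif col == "tR_min":
                    parsed[col] = np.nan if val == "" else _parse_float(
                        val, path, lineno, col
                    )
                elif col in numeric:
                    parsed[col] = _parse_float(val, path, lineno, col)
                else:  # extra columns (e.g. area) parsed as float when possible
                    try:
                        parsed[col] = float(val)
                    except ValueError:
                        parsed[col] = val
            rows.append(parsed)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return RunTable(pd.DataFrame(rows))


def _parse_float(val: str, path: Path, lineno: int, col: str) -> float:
    try:
        return float(val)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: non-numeric value {val!r} in column {col!r}"
        ) from None


def write_run_table(table: RunTable, path: PathLike) -> None:
    """Write a run table back to CSV (full precision, blank for missing)."""
    frame = table.frame[RUN_TABLE_COLUMNS]
    frame.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Fitted model serialization
# ---------------------------------------------------------------------------


def model_to_json(model: FittedModel, path: PathLike) -> None:
    design = model.design
    payload = {
        "design": {
            "tG_levels": list(design.tG_levels),
            "T_levels": list(design.T_levels),
            "pH_levels": list(design.pH_levels),
            "flow_mL_min": design.flow_mL_min,
            "pctB_start": 100.0 * design.phi_start,
            "pctB_end": 100.0 * design.phi_end,
        },
        "compounds": {
            compound: {
                f"{ti},{pj}": (
                    None
                    if solute is None
                    else {"log_kw": solute.log_kw, "S": solute.S}
                )
                for (ti, pj), solute in corners.items()
            }
            for compound, corners in model.params.items()
        },
        "diagnostics": model.diagnostics.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def model_from_json(path: PathLike) -> FittedModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    d = payload["design"]
    design = CalibrationDesign(
        tG_levels=tuple(d["tG_levels"]),
        T_levels=tuple(d["T_levels"]),
        pH_levels=tuple(d["pH_levels"]),
        flow_mL_min=d["flow_mL_min"],
        phi_start=d["pctB_start"] / 100.0,
        phi_end=d["pctB_end"] / 100.0,
    )
    params = {}
    for compound, corners in payload["compounds"].items():
        out = {}
        for key, val in corners.items():
            ti, pj = (int(x) for x in key.split(","))
            out[(ti, pj)] = None if val is None else SoluteLSS(val["log_kw"], val["S"])
        params[compound] = out
    diagnostics = pd.DataFrame(payload.get("diagnostics", []))
    return FittedModel(design=design, params=params, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Report CSV / JSON writers
# ---------------------------------------------------------------------------


def write_chromatogram_csv(
    chrom: Chromatogram, path: PathLike, report: bool = False
) -> None:
    """Peak table CSV; ``report=True`` uses 2-decimal retention times."""
    chrom.to_frame(report=report).to_csv(path, index=False)


def write_map_csv(dsmap: DesignSpaceMap, path: PathLike) -> None:
    frame = dsmap.to_frame()
    frame["Rs_crit"] = frame["Rs_crit"].round(2)
    frame.to_csv(path, index=False)


def write_robustness_csv(result: RobustnessResult, path: PathLike) -> None:
    table = result.table.copy()
    table["Rs_crit"] = table["Rs_crit"].round(2)
    table.to_csv(path, index=False)


def write_working_point_json(wp: WorkingPoint, path: PathLike) -> None:
    cond = wp.conditions
    payload = {
        "tG_min": cond.tG_min,
        "T_C": cond.T_C,
        "pH": cond.pH,
        "flow_mL_min": cond.flow_mL_min,
        "pctB_start": 100.0 * cond.phi_start,
        "pctB_end": 100.0 * cond.phi_end,
        "Rs_crit": wp.rs_crit,
        "robustness_radius": wp.robustness_radius,
        "critical_pair": list(wp.critical_pair),
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_config(path: PathLike) -> ProjectConfig:
    """Load and validate a YAML/JSON project config; unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    try:
        return ProjectConfig.model_validate(raw)
    except ValidationError as exc:
        raise InputError(f"invalid config {path}: {exc}") from exc
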