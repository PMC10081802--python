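"""Cohort and result-table I/O, configuration loading, report bundle.

Missing values are encoded as empty CSV fields throughout — no numeric
sentinels, so a sentinel can never be scored by accident. All result tables
are long/tidy; the wide Table-1-style layout is produced only in the report
step.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .pipeline import AnalysisConfig
from .simulate import SimulationConfig, SCORE_DOMAINS

__all__ = [
    "CohortReadResult",
    "ReportBundle",
    "read_cohort",
    "write_cohort",
    "load_config",
    "write_report",
]

log = logging.getLogger("tbisens")

MANDATORY_COLUMNS = (
    "subject_id", "timepoint_months", "sex", "age_years", "education",
    "premorbid_psych", "pathway", "gcs", "ct_abnormal", "iss",
)

_CATEGORICAL = {
    "sex": {"male", "female"},
    "education": {"primary_or_less", "at_least_secondary"},
    "premorbid_psych": {"absent", "present"},
    "pathway": {"ER", "ADM", "ICU"},
}


@dataclass
class CohortReadResult:
    """Validated cohort plus row-level diagnostics.

    ``errors`` holds ``(line_number, message)`` for every rejected row;
    line numbers refer to the CSV file (header = line 1).
    """

    frame: pd.DataFrame
    errors: list[tuple[int, str]] = field(default_factory=list)


def read_cohort(path, strict: bool = False) -> CohortReadResult:
    """Read and validate a long-format cohort CSV.

    Mandatory columns must be present (missing ones raise, naming the
    column). Malformed rows — GCS outside 3-15, unknown categorical levels,
    a time point outside {3, 6, 12}, negative ISS — are dropped and reported
    with their line numbers; ``strict=True`` raises on the first such row.
    Unknown columns are preserved untouched.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        log.warning("empty cohort file %s", path)
        return CohortReadResult(pd.DataFrame(columns=list(MANDATORY_COLUMNS)))
    if frame.empty and not frame.columns.size:
        log.warning("empty cohort file %s", path)
        return CohortReadResult(pd.DataFrame(columns=list(MANDATORY_COLUMNS)))
    for col in MANDATORY_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"mandatory column {col!r} missing from {path}")
    errors: list[tuple[int, str]] = []
    bad = np.zeros(len(frame), dtype=bool)

    def reject(mask: pd.Series, message: str) -> None:
        for pos in frame.index[mask & ~bad]:
            errors.append((int(pos) + 2, message))  # +2: header + 1-based
        bad[mask.to_numpy()] = True

    gcs = pd.to_numeric(frame["gcs"], errors="coerce")
    reject(gcs.notna() & ~gcs.between(3, 15), "gcs outside the valid range 3-15")
    tp = pd.to_numeric(frame["timepoint_months"], errors="coerce")
    reject(~tp.isin([3, 6, 12]), "timepoint_months not in {3, 6, 12}")
    iss = pd.to_numeric(frame["iss"], errors="coerce")
    reject(iss.notna() & (iss < 0), "iss must be non-negative")
    for col, allowed in _CATEGORICAL.items():
        vals = frame[col]
        reject(vals.notna() & ~vals.isin(sorted(allowed)),
               f"{col} not one of {sorted(allowed)}")
    dup = frame.duplicated(subset=["subject_id", "timepoint_months"], keep="first")
    reject(dup, "duplicate subject_id x timepoint_months record")
    if errors and strict:
        line, message = errors[0]
        raise ValueError(f"{path}:{line}: {message}")
    kept = frame[~bad].reset_index(drop=True)
    if len(kept) == 0 and len(frame) == 0:
        log.warning("cohort file %s contains no rows", path)
    return CohortReadResult(kept, errors)


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write a cohort CSV with empty fields for missing values."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, na_rep="")


# --- configuration -----------------------------------------------------------

def _apply_overrides(obj, data: Mapping, context: str):
    valid = {f.name for f in dataclasses.fields(obj)}
    updates = {}
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"{context}.{key}: unknown configuration field")
        current = getattr(obj, key)
        if isinstance(current, tuple) and isinstance(value, list):
            value = tuple(value)
        if key == "sigma":
            value = np.asarray(value, dtype=float)
        if key == "effects" and isinstance(value, Mapping):
            parsed = {}
            for k, spec in value.items():
                factor, _, level = str(k).partition(":")
                if not level:
                    raise ValueError(f"{context}.effects.{k}: expected 'factor:level' key")
                parsed[(factor, level)] = dict(spec)
            value = parsed
        if key == "missingness" and isinstance(value, Mapping):
            value = {instr: ({int(t): float(r) for t, r in rate.items()}
                             if isinstance(rate, Mapping) else float(rate))
                     for instr, rate in value.items()}
        if key == "time_trend" and isinstance(value, Mapping):
            value = {int(t): float(v) for t, v in value.items()}
        updates[key] = value
    try:
        return dataclasses.replace(obj, **updates)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{context}: {exc}") from exc


def load_config(path) -> AnalysisConfig | SimulationConfig:
    """Load an analysis or simulation configuration from YAML.

    The file holds a single top-level block, ``analysis:`` or
    ``simulation:``; omitted fields keep the published defaults (effect
    bands 0.29/0.36/0.64/0.71, alphas 0.00045/0.0001/0.005, clinical
    cut-offs). The effective configuration is echoed to the log so any run
    can be reproduced from the log alone.
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ValueError(f"{path}: malformed YAML: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a mapping at the top level")
    keys = set(data)
    if keys == {"analysis"} or not keys:
        cfg = _apply_overrides(AnalysisConfig(), data.get("analysis") or {}, "analysis")
    elif keys == {"simulation"}:
        cfg = _apply_overrides(SimulationConfig(), data.get("simulation") or {},
                               "simulation")
        cfg.validate()
    else:
        raise ValueError(
            f"{path}: expected a single top-level 'analysis' or 'simulation' block")
    log.info("effective config from %s: %s", path, config_digest(cfg)[1])
    return cfg


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, Mapping):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, (np.integer, np.floating)):
        return value.item()
    return value


def config_digest(cfg) -> tuple[str, str]:
    """(sha256 hash, canonical JSON echo) of a configuration object."""
    payload = {f.name: _jsonable(getattr(cfg, f.name))
               for f in dataclasses.fields(cfg)}
    blob = json.dumps({type(cfg).__name__: payload}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest(), blob


# --- report bundle -----------------------------------------------------------

@dataclass
class ReportBundle:
    """Everything one run produces, ready to serialize."""

    sensitivity: pd.DataFrame
    effects: pd.DataFrame
    pooled: pd.DataFrame
    recommendations: pd.DataFrame
    prevalence: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _table1_text(sensitivity: pd.DataFrame) -> str:
    """Wide instrument x time-point sensitivity layout with top-3 markers."""
    if sensitivity.empty:
        return "no feasible comparisons\n"
    wide = sensitivity.pivot(index="instrument", columns="timepoint",
                             values="percent")
    tps = [c for c in wide.columns if c != "average"] + (
        ["average"] if "average" in wide.columns else [])
    wide = wide[tps]
    ranked = {}
    for tp in tps:
        order = wide[tp].rank(ascending=False, method="min")
        ranked[tp] = order <= 3
    lines = ["Overall sensitivity: percent of feasible pairwise comparisons "
             "with at least a medium MW effect",
             "(* marks the top three instruments per column)", ""]
    header = f"{'instrument':<12}" + "".join(f"{str(tp) + ' mo' if tp != 'average' else 'average':>10}"
                                             for tp in tps)
    lines.append(header)
    for instrument, row in wide.iterrows():
        cells = []
        for tp in tps:
            v = row[tp]
            mark = "*" if ranked[tp].get(instrument, False) and not pd.isna(v) else " "
            cells.append(f"{'--' if pd.isna(v) else format(round(v), 'd') + '%'}{mark}".rjust(10))
        lines.append(f"{instrument:<12}" + "".join(cells))
    return "\n".join(lines) + "\n"


def write_report(bundle: ReportBundle, out_dir) -> dict[str, Path]:
    """Write the report bundle: one CSV per table with a stable column
    order, a Table-1-style plain-text summary, and run metadata JSON.
    Re-running with identical inputs reproduces identical files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    tables = {
        "sensitivity": bundle.sensitivity,
        "effects": bundle.effects,
        "pooled_forest": bundle.pooled,
        "recommendations": bundle.recommendations,
        "prevalence": bundle.prevalence,
    }
    for name, frame in tables.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False, na_rep="")
        written[name] = path
    summary = out / "summary.txt"
    summary.write_text(_table1_text(bundle.sensitivity))
    written["summary"] = summary
    meta = out / "run_metadata.json"
    meta.write_text(json.dumps(_jsonable(bundle.metadata), indent=2, sort_keys=True))
    written["metadata"] = meta
    return written
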