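"""Readers and writers for trace files and cohort tables.

Trace files are two-column delimited text (``time_s`` plus either
``intensity_au`` for raw traces or ``f`` for processed ones) preceded
by a single ``#``-prefixed JSON metadata line.  The delimiter is
auto-detected between comma and tab.  Cohort tables are CSV with a
fixed header mirroring the per-cell fit summaries (one row per cell,
condition and phase; unused parameter cells left empty).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .kinetics import KineticFit, derived_metrics
from .trace import ProcessedTrace, RawTrace, TraceValidationError

__all__ = [
    "SchemaError",
    "read_trace",
    "write_trace",
    "read_cohort",
    "write_cohort",
    "cohort_record",
    "cohort_from_fits",
]

COHORT_COLUMNS = [
    "cell_id", "cell_type", "condition", "phase", "model",
    "P", "Q", "A", "B", "C", "D", "R", "plateau", "half_time_s", "flags",
]
_COHORT_NUMERIC = ["P", "Q", "A", "B", "C", "D", "R", "plateau", "half_time_s"]


class SchemaError(ValueError):
    """A file does not conform to the expected on-disk schema."""


def write_trace(trace: RawTrace | ProcessedTrace, path: str | Path, delimiter: str = ",") -> Path:
    """Write a trace as delimited text with a JSON metadata header line."""
    path = Path(path)
    if isinstance(trace, RawTrace):
        value_col, values = "intensity_au", trace.intensities
        meta = {"kind": "raw", **trace.metadata}
    else:
        value_col, values = "f", trace.f
        meta = {
            "kind": "processed",
            "normalization_constant": trace.normalization_constant,
            "n_spikes_removed": trace.n_spikes_removed,
            **trace.metadata,
        }
    lines = ["# " + json.dumps(meta, default=_json_default)]
    lines.append(f"time_s{delimiter}{value_col}")
    for t, v in zip(trace.times, values):
        lines.append(f"{float(t)!r}{delimiter}{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _detect_delimiter(header_line: str) -> str:
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    raise SchemaError(f"cannot detect delimiter in header line {header_line!r}")


def read_trace(path: str | Path) -> RawTrace | ProcessedTrace:
    """Read a trace file, returning a RawTrace or ProcessedTrace by kind.

    Schema errors (missing columns, non-monotone times, non-numeric
    values) name the offending line number.
    """
    path = Path(path)
    meta: dict = {}
    header: list[str] | None = None
    delim = ","
    times: list[float] = []
    values: list[float] = []
    linenos: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                payload = line.lstrip("#").strip()
                if payload:
                    try:
                        meta.update(json.loads(payload))
                    except json.JSONDecodeError as exc:
                        raise SchemaError(f"line {lineno}: bad JSON metadata header: {exc}") from exc
                continue
            if header is None:
                delim = _detect_delimiter(line)
                header = [c.strip() for c in line.split(delim)]
                if header[0] != "time_s" or len(header) != 2 or header[1] not in ("intensity_au", "f"):
                    raise SchemaError(
                        f"line {lineno}: expected columns 'time_s' and 'intensity_au' or 'f', got {header}"
                    )
                continue
            parts = line.split(delim)
            if len(parts) != 2:
                raise SchemaError(f"line {lineno}: expected 2 columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
                linenos.append(lineno)
            except ValueError as exc:
                raise SchemaError(f"line {lineno}: non-numeric value: {exc}") from exc
    if header is None:
        raise SchemaError(f"{path}: no header line found")
    t = np.asarray(times)
    if t.size >= 2:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise SchemaError(
                f"times not strictly increasing at line {linenos[int(bad[0]) + 1]} of {path.name}"
            )
    kind = meta.pop("kind", "raw" if header[1] == "intensity_au" else "processed")
    try:
        if kind == "raw":
            return RawTrace(t, np.asarray(values), meta)
        return ProcessedTrace(
            times=t,
            f=np.asarray(values),
            n_spikes_removed=int(meta.pop("n_spikes_removed", 0)),
            normalization_constant=float(meta.pop("normalization_constant", 1.0)),
            metadata=meta,
        )
    except TraceValidationError as exc:
        raise SchemaError(str(exc)) from exc


def cohort_record(
    cell_id: str, cell_type: str, condition: str, phase: str, fit: KineticFit
) -> dict:
    """One cohort-table row from a kinetic fit."""
    row = {c: None for c in COHORT_COLUMNS}
    row.update(cell_id=cell_id, cell_type=cell_type, condition=condition,
               phase=phase, model=fit.model_kind, R=fit.R,
               flags=";".join(fit.flags))
    if fit.model_kind == "one_exp":
        row["P"], row["Q"] = fit.params
    else:
        row["A"], row["B"], row["C"], row["D"] = fit.params
    try:
        metrics = derived_metrics(fit)
        row["plateau"] = metrics["plateau"]
        row["half_time_s"] = metrics["half_time_s"]
    except Exception:
        row["plateau"] = fit.plateau
    return row


def cohort_from_fits(records: Iterable[tuple[str, str, str, str, KineticFit]]) -> pd.DataFrame:
    """Cohort table from (cell_id, cell_type, condition, phase, fit) tuples."""
    rows = [cohort_record(*rec) for rec in records]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort table as CSV with the fixed schema header."""
    path = Path(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns {missing}")
    _validate_cohort(table)
    table = table[COHORT_COLUMNS]
    table.to_csv(path, index=False, float_format="%.12g")
    return path


def _validate_cohort(df: pd.DataFrame) -> None:
    keys = df[["cell_id", "condition", "phase"]].astype(str).agg("|".join, axis=1)
    dup = keys[keys.duplicated()]
    if not dup.empty:
        raise SchemaError(f"duplicate (cell_id, condition, phase) keys: {sorted(set(dup))}")
    for col in _COHORT_NUMERIC:
        bad = df[col].map(
            lambda v: v is not None
            and not (isinstance(v, float) and math.isnan(v))
            and not isinstance(v, (int, float, np.integer, np.floating))
        )
        if bad.any():
            raise SchemaError(f"non-numeric value in column {col!r}")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and schema-validate a cohort CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"cell_id": str, "cell_type": str,
                                      "condition": str, "phase": str, "flags": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty cohort file") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: cohort has no rows")
    for col in _COHORT_NUMERIC:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: non-numeric value in column {col!r}: {exc}") from exc
    _validate_cohort(df)
    df["flags"] = df["flags"].fillna("")
    return df
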