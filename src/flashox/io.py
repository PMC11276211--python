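"""Readers and writers for the package's CSV/JSON formats.

Formats (times in milliseconds throughout):

* flash-pattern CSV: columns ``flash, amplitude[, error]``; header required;
  flash indices are 1-based and contiguous.
* kinetics CSV: columns ``dt_ms, y3, replicate, series, is_standard,
  varied_pair``.
* protocol JSON: ``{"n_flashes", "base_interval_ms", "varied_pair",
  "varied_interval_ms"}`` with ``varied_pair`` null for the standard train.
* fit-report JSON: versioned schema with model kind, named parameters,
  pfq, residuals and convergence diagnostics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataSchemaError
from .fitting import FitResult
from .kinetics import KineticsDataset
from .sstate import FlashPattern, FlashProtocol

__all__ = [
    "RunConfig", "read_run_config",
    "read_pattern_csv", "write_pattern_csv",
    "read_kinetics_csv", "write_kinetics_csv",
    "read_protocol_json", "write_protocol_json",
    "write_fit_report", "read_fit_report",
]

logger = logging.getLogger("flashox")

FIT_REPORT_SCHEMA_VERSION = 1

_RUN_CONFIG_KEYS = {
    "model", "row", "pattern_csv", "protocol", "seed", "out_dir", "verbose",
}
_RUN_MODELS = ("five_s", "kok", "kok2")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a simulate-or-load -> fit -> report run.

    Exactly one of ``row`` (simulate from a preparation preset) or
    ``pattern_csv`` (load a measured pattern) must be given.  Unknown keys
    in the JSON are rejected before any computation happens.
    """

    model: str = "five_s"
    row: str | None = None
    pattern_csv: str | None = None
    protocol: dict | None = None
    seed: int = 0
    out_dir: str = "results"
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.model not in _RUN_MODELS:
            raise DataSchemaError(f"model must be one of {_RUN_MODELS}, got {self.model!r}")
        if (self.row is None) == (self.pattern_csv is None):
            raise DataSchemaError("exactly one of 'row' or 'pattern_csv' is required")
        if not isinstance(self.seed, int):
            raise DataSchemaError("seed must be an integer")


def read_run_config(path) -> RunConfig:
    with open(path) as fh:
        payload = json.load(fh)
    unknown = set(payload) - _RUN_CONFIG_KEYS
    if unknown:
        raise DataSchemaError(f"{path}: unknown run-config keys {sorted(unknown)}")
    return RunConfig(**payload)


def read_pattern_csv(path) -> FlashPattern:
    """Read a per-flash amplitude table (columns flash, amplitude[, error])."""
    try:
        df = pd.read_csv(path)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise DataSchemaError(f"cannot parse {path}: {exc}") from exc
    for col in ("flash", "amplitude"):
        if col not in df.columns:
            raise DataSchemaError(f"{path}: missing required column '{col}'")
    for col in [c for c in ("flash", "amplitude", "error") if c in df.columns]:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise DataSchemaError(f"{path}: column '{col}' contains non-numeric cells")
    flashes = df["flash"].to_numpy()
    expected = np.arange(1, len(df) + 1)
    df = df.sort_values("flash")
    if not np.array_equal(np.sort(flashes), expected):
        raise DataSchemaError(
            f"{path}: flash indices must be contiguous 1..{len(df)}, got {sorted(flashes)}"
        )
    errors = df["error"].to_numpy(dtype=float) if "error" in df.columns else None
    amps = df["amplitude"].to_numpy(dtype=float)
    norm = "y3" if len(amps) >= 3 and abs(amps[2] - 1.0) <= 1e-9 else "raw"
    return FlashPattern(amps, errors=errors, normalization=norm)


def write_pattern_csv(pattern: FlashPattern, path) -> None:
    df = pd.DataFrame({
        "flash": np.arange(1, pattern.n_flashes + 1),
        "amplitude": pattern.amplitudes,
    })
    if pattern.errors is not None:
        df["error"] = pattern.errors
    df.to_csv(path, index=False, float_format="%.12g")


def read_kinetics_csv(path) -> KineticsDataset:
    """Read a Y3-versus-interval table.

    Out-of-range dt values are warned about but kept; duplicate
    (series, replicate, dt_ms, is_standard) rows are rejected.
    """
    df = pd.read_csv(path)
    required = ["dt_ms", "y3", "replicate", "series", "is_standard", "varied_pair"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataSchemaError(f"{path}: missing required columns {missing}")
    for col in ("dt_ms", "y3"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise DataSchemaError(f"{path}: column '{col}' contains non-numeric cells")
    out_of_range = (df["dt_ms"] < 5) | (df["dt_ms"] > 500)
    if out_of_range.any():
        logger.warning(
            "%s: %d rows with dt_ms outside [5, 500] ms kept as-is",
            path, int(out_of_range.sum()),
        )
    key = ["series", "replicate", "dt_ms", "is_standard"]
    dupes = df.duplicated(subset=key)
    if dupes.any():
        raise DataSchemaError(
            f"{path}: duplicate (series, replicate, dt_ms) rows: "
            f"{df.loc[dupes, key].to_dict('records')}"
        )
    pairs = set(df["varied_pair"].unique())
    if not pairs <= {"1-2", "2-3"}:
        raise DataSchemaError(f"{path}: varied_pair must be '1-2' or '2-3', got {pairs}")
    varied_pair = df["varied_pair"].iloc[0] if len(pairs) == 1 else "2-3"
    df = df.drop(columns=["varied_pair"])
    df["is_standard"] = df["is_standard"].astype(bool)
    return KineticsDataset(df, varied_pair=varied_pair, normalization_state="scaled")


def write_kinetics_csv(ds: KineticsDataset, path) -> None:
    df = ds.data.copy()
    df["varied_pair"] = ds.varied_pair
    df.to_csv(path, index=False, float_format="%.12g")


def read_protocol_json(path) -> FlashProtocol:
    with open(path) as fh:
        payload = json.load(fh)
    known = {"n_flashes", "base_interval_ms", "varied_pair", "varied_interval_ms"}
    unknown = set(payload) - known
    if unknown:
        raise DataSchemaError(f"{path}: unknown protocol keys {sorted(unknown)}")
    n = int(payload.get("n_flashes", 16))
    base = float(payload.get("base_interval_ms", 300.0))
    pair = payload.get("varied_pair")
    if pair is None:
        return FlashProtocol.standard(n, base)
    return FlashProtocol.with_varied_interval(
        pair, float(payload["varied_interval_ms"]), n_flashes=n, base_interval_ms=base
    )


def write_protocol_json(protocol: FlashProtocol, path) -> None:
    times = protocol.flash_times
    gaps = [b - a for a, b in zip(times, times[1:])]
    base = max(set(gaps), key=gaps.count) if gaps else 300.0
    varied = [(i, g) for i, g in enumerate(gaps) if abs(g - base) > 1e-9]
    payload = {
        "n_flashes": protocol.count,
        "base_interval_ms": base,
        "varied_pair": None,
        "varied_interval_ms": None,
    }
    if len(varied) == 1 and varied[0][0] in (0, 1):
        payload["varied_pair"] = "1-2" if varied[0][0] == 0 else "2-3"
        payload["varied_interval_ms"] = varied[0][1]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def _jsonify(value):
    if isinstance(value, np.ndarray):
        return [None if not np.isfinite(v) else float(v) for v in value]
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, dict):
        return {k: _jsonify(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonify(v) for v in value]
    return value


def write_fit_report(result: FitResult, path) -> None:
    """Serialize a FitResult to versioned JSON."""
    report = {
        "schema_version": FIT_REPORT_SCHEMA_VERSION,
        "model_kind": result.model_kind,
        "params": _jsonify(result.params),
        "pfq": float(result.pfq),
        "residuals": _jsonify(result.residuals),
        "n_free": int(result.n_free),
        "converged": bool(result.converged),
        "n_evaluations": int(result.n_evaluations),
    }
    stderr = result.extra.get("stderr")
    if stderr is not None:
        report["stderr"] = _jsonify(stderr)
    if "degenerate" in result.extra:
        report["degenerate"] = bool(result.extra["degenerate"])
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def read_fit_report(path) -> dict:
    with open(path) as fh:
        report = json.load(fh)
    if report.get("schema_version") != FIT_REPORT_SCHEMA_VERSION:
        raise DataSchemaError(
            f"{path}: unsupported fit report schema {report.get('schema_version')!r}"
        )
    return report
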