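"""Configuration files, table formats, structured records, run manifests.

One flat plain-text config format (``key: value``, YAML-compatible) serves
every module; unknown keys are rejected, missing keys fall back to the
baseline preset.  Event tables travel as UTF-8 comma-delimited text with a
header row; fits and summaries as JSON documents with a schema version.
Every CLI command writes a manifest recording parameters, seeds and file
digests so any output can be regenerated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinetics import EventTable
from .lattice import (
    EnergyParams,
    LatticeGeometry,
    baseline_params,
    xmap215_ablong_only_params,
    xmap215_params,
)

__all__ = [
    "PRESETS",
    "load_config",
    "save_config",
    "write_event_tables",
    "read_event_tables",
    "write_record",
    "read_record",
    "import_workbook",
    "write_manifest",
]

PRESETS = {
    "baseline": baseline_params,
    "xmap215": xmap215_params,
    "xmap215-ablong-only": xmap215_ablong_only_params,
    # the seed preset shares baseline energies; the engine overrides the
    # γ-bond and the starting conformation in seed mode
    "seed": baseline_params,
}

_PARAM_KEYS = {
    "k_on": "k_on",
    "dG_long_ab": "dG_long_ab",
    "dG_lat_ab": "dG_lat_ab",
    "dG_long_gamma": "dG_long_gamma",
    "dG_conf": "dG_conf",
    "k_conf": "k_conf",
    "closure_sign": "closure_sign",
}
_GEOM_KEYS = {"n_pf", "seam_offset_dimers", "dimer_rise_nm"}


def load_config(path: str | Path | None = None, preset: str = "baseline") -> Tuple[EnergyParams, LatticeGeometry]:
    """Read a flat config mapping into validated parameter structures.

    An empty (or missing) config yields the full baseline preset.  Unknown
    keys raise with the offending key named; invariant violations (wrong
    sign, negative barrier) surface from the dataclass validators."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    raw: Dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a flat key: value mapping")
    preset_name = raw.pop("preset", preset)
    if preset_name not in PRESETS:
        raise ValueError(f"unknown preset {preset_name!r}; choose from {sorted(PRESETS)}")
    params = PRESETS[preset_name]()
    unknown = set(raw) - set(_PARAM_KEYS) - _GEOM_KEYS
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; allowed: "
            f"{sorted(set(_PARAM_KEYS) | _GEOM_KEYS | {'preset'})}"
        )
    overrides = {k: raw[k] for k in _PARAM_KEYS if k in raw}
    if overrides:
        params = params.replace(**overrides)
    geom_kwargs = {k: raw[k] for k in _GEOM_KEYS if k in raw}
    geometry = LatticeGeometry(**geom_kwargs)
    return params, geometry


def save_config(path: str | Path, params: EnergyParams, geometry: LatticeGeometry = LatticeGeometry()) -> None:
    data = {**asdict(params), **asdict(geometry)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_event_tables(path: str | Path, tables: Sequence[EventTable]) -> None:
    """Write event tables as comma-delimited text (full-precision times)."""
    frames = [t.to_frame() for t in tables]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["condition", "concentration_uM", "nucleation_time_s", "censor_time_s", "n0"]
    )
    df.to_csv(path, index=False)  # pandas writes shortest round-trip floats


def read_event_tables(path: str | Path) -> List[EventTable]:
    """Read the delimited event-table format back into EventTable objects,
    grouped by (condition, concentration)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # surface parse errors with file context
        raise ValueError(f"malformed event table {path}: {exc}") from exc
    required = {"condition", "concentration_uM", "nucleation_time_s", "censor_time_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event table {path} is missing column(s) {sorted(missing)}")
    tables: List[EventTable] = []
    df["condition"] = df["condition"].fillna("")
    for (cond, conc), grp in df.groupby(["condition", "concentration_uM"], sort=True):
        n0 = None
        if "n0" in grp.columns and grp["n0"].notna().any():
            n0 = int(grp["n0"].dropna().iloc[0])
        times = grp["nucleation_time_s"].dropna().to_numpy()
        tables.append(
            EventTable(
                concentration=float(conc),
                times=times,
                censor_time=float(grp["censor_time_s"].iloc[0]),
                n0=n0,
                condition=str(cond),
            )
        )
    return tables


def write_record(path: str | Path, record: dict) -> None:
    record = dict(record)
    record.setdefault("schema_version", 1)
    Path(path).write_text(json.dumps(record, indent=2, default=_json_default) + "\n")


def read_record(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed record {path}: line {exc.lineno}, column {exc.colno}") from exc


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def import_workbook(
    path: str | Path,
    sheet: str | int = 0,
    censor_time: Optional[float] = None,
    n0: Optional[int] = None,
    condition: str = "",
) -> List[EventTable]:
    """Import a source-data spreadsheet sheet into event tables.

    Two layouts are recognised: *long* (same columns as the CSV dialect:
    condition, concentration_uM, nucleation_time_s, censor_time_s, n0) and
    *wide* (one column per concentration, header parseable as μM, cells
    holding nucleation times; ``censor_time`` and optionally ``n0`` then
    come from the caller)."""
    df = pd.read_excel(path, sheet_name=sheet)
    if "nucleation_time_s" in df.columns:
        # long layout: reuse the CSV reader via an in-memory buffer
        import io as _io

        buf = _io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return read_event_tables(buf)  # type: ignore[arg-type]
    if censor_time is None:
        raise ValueError("wide-layout import requires an explicit censor_time")
    tables = []
    for col in df.columns:
        try:
            conc = float(str(col).replace("uM", "").replace("µM", "").strip())
        except ValueError as exc:
            raise ValueError(f"column header {col!r} is not a concentration in uM") from exc
        times = pd.to_numeric(df[col], errors="coerce").dropna().to_numpy()
        tables.append(
            EventTable(
                concentration=conc,
                times=times,
                censor_time=censor_time,
                n0=n0,
                condition=condition,
            )
        )
    return tables


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    parameters: dict,
    master_seed: Optional[int] = None,
    inputs: Sequence[str | Path] = (),
    outputs: Sequence[str | Path] = (),
) -> dict:
    """Write a reproducibility manifest next to a command's outputs."""
    manifest = {
        "schema_version": 1,
        "command": command,
        "parameters": parameters,
        "master_seed": master_seed,
        "code_version": __version__,
        "python": platform.python_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": {str(p): _digest(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _digest(Path(p)) for p in outputs if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=_json_default) + "\n")
    return manifest
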