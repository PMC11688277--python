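"""Readers/writers for all file artifacts plus run manifests.

CSV dialect is fixed: UTF-8, comma separator, header row, '.' decimal, float
time column.  Manifests are JSON with sorted keys and contain no timestamps or
absolute paths, so identical runs produce byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import os
from importlib.metadata import PackageNotFoundError, version
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .dynamics import HealthState
from .exceptions import ConfigurationError
from .monitoring import AlertEvent, SensorSeries

__all__ = [
    "read_yaml",
    "validate_keys",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_sensor_csv",
    "read_sensor_csv",
    "write_drivers_csv",
    "read_drivers_csv",
    "write_json",
    "read_json",
    "write_alerts_jsonl",
    "read_alerts_jsonl",
    "sha256_file",
    "write_manifest",
]

# 17 significant digits: every float64 survives the CSV round-trip exactly
FLOAT_FMT = "%.17g"


def read_yaml(path: str) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return cfg


def validate_keys(cfg: dict, allowed: set[str], required: set[str], context: str) -> None:
    """Schema guard: unknown keys are rejected, required keys must be present."""
    unknown = set(cfg) - allowed
    if unknown:
        raise ConfigurationError(f"{context}: unknown keys {sorted(unknown)}")
    missing = required - set(cfg)
    if missing:
        raise ConfigurationError(f"{context}: missing required keys {sorted(missing)}")


def _write_df(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_trajectory_csv(path: str, traj: HealthState) -> None:
    _write_df(pd.DataFrame({"t": traj.t, "H": traj.H}), path)


def read_trajectory_csv(path: str) -> HealthState:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"t", "H"} <= set(df.columns):
        raise ConfigurationError(f"{path}: trajectory CSV needs columns t, H")
    return HealthState(t=df["t"].to_numpy(), H=df["H"].to_numpy())


def write_sensor_csv(path: str, series: SensorSeries) -> None:
    _write_df(
        pd.DataFrame(
            {"t": series.t, "value": series.values, "observed_flag": series.mask.astype(int)}
        ),
        path,
    )


def read_sensor_csv(path: str, channel: Optional[str] = None) -> SensorSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"t", "value"} <= set(df.columns):
        raise ConfigurationError(f"{path}: sensor CSV needs columns t, value[, observed_flag]")
    mask = (
        df["observed_flag"].to_numpy().astype(bool) if "observed_flag" in df.columns else None
    )
    name = channel or os.path.splitext(os.path.basename(path))[0]
    return SensorSeries(
        t=df["t"].to_numpy(), values=df["value"].to_numpy(), mask=mask, channel=name
    )


DRIVER_COLUMNS = ("S", "P", "E_env", "C_exo", "R_exo", "Sc", "Rm")


def write_drivers_csv(path: str, t: np.ndarray, columns: dict[str, np.ndarray]) -> None:
    data = {"t": np.asarray(t, dtype=float)}
    for name, vals in columns.items():
        if name not in DRIVER_COLUMNS:
            raise ConfigurationError(f"unknown driver column '{name}'")
        data[name] = np.asarray(vals, dtype=float)
    _write_df(pd.DataFrame(data), path)


def read_drivers_csv(path: str):
    """Read a driver table (t plus any of S, P, E_env, C_exo, R_exo, Sc, Rm)."""
    from .dynamics import DriverSignals

    df = pd.read_csv(path, float_precision="round_trip")
    if "t" not in df.columns:
        raise ConfigurationError(f"{path}: drivers CSV needs a 't' column")
    t = df["t"].to_numpy(dtype=float)
    kwargs = {}
    for col in df.columns:
        if col == "t":
            continue
        if col not in DRIVER_COLUMNS:
            raise ConfigurationError(f"{path}: unknown driver column '{col}'")
        kwargs[col] = (t, df[col].to_numpy(dtype=float))
    return DriverSignals(**kwargs)


def write_json(path: str, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str):
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def write_alerts_jsonl(path: str, events: list[AlertEvent]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(
                json.dumps(
                    {
                        "t_start": ev.t_start,
                        "t_end": ev.t_end,
                        "severity": ev.severity,
                        "evidence": ev.evidence,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_alerts_jsonl(path: str) -> list[AlertEvent]:
    events = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                events.append(
                    AlertEvent(
                        t_start=d["t_start"],
                        t_end=d["t_end"],
                        severity=d["severity"],
                        evidence=d.get("evidence", {}),
                    )
                )
    return events


def sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _version() -> str:
    try:
        return version("eldersim")
    except PackageNotFoundError:
        return "unknown"


def write_manifest(
    path: str,
    command: str,
    config: dict,
    inputs: dict[str, str],
    outputs: dict[str, str],
    seed: Optional[int] = None,
) -> None:
    """Record a run: resolved config, input/output basenames with checksums.

    Only basenames are stored, never directories, so manifests from identical
    runs in different working directories compare byte-equal.
    """
    manifest = {
        "command": command,
        "config": config,
        "inputs": {os.path.basename(p): sha256_file(p) for p in inputs.values()},
        "outputs": {os.path.basename(p): sha256_file(p) for p in outputs.values()},
        "seed": seed,
        "version": _version(),
    }
    write_json(path, manifest)
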