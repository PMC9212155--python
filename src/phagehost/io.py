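"""Configuration loading and CSV input/output.

Configuration files are TOML with one key per model parameter, named exactly
as the fields of :class:`~phagehost.params.SimulationParams` (e.g. ``omega``,
``N_v0``, ``compatibility_mode``).  Absent keys take the standard defaults;
unknown keys are an error.

The plate-reader CSV reader expects the columns ``time`` (hours), ``vhr``
(virus-to-host-ratio label; the uninfected control may be labelled
``control``), ``n`` (replicates), ``mean`` and ``sd`` (OD600).  OD600 is a
proxy for host abundance; no unit conversion is attempted.
"""

from __future__ import annotations

import tomllib
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Trajectory
from .params import SimulationParams, validate

__all__ = [
    "ConfigError",
    "load_config",
    "read_experimental_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

EXPERIMENTAL_COLUMNS = ("time", "vhr", "n", "mean", "sd")


class ConfigError(ValueError):
    """Raised for malformed configuration or data files."""


def load_config(path) -> SimulationParams:
    """Load a TOML parameter file, fill defaults, and validate.

    Raises :class:`ConfigError` naming the offending key for unknown keys,
    type mismatches, or invariant violations.
    """
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: not valid TOML ({exc})") from exc
    known = {f.name: f.type for f in fields(SimulationParams)}
    unknown = sorted(set(raw) - set(known))
    if unknown:
        raise ConfigError(f"{path}: unknown key(s): {', '.join(unknown)}")
    coerced = {}
    for key, value in raw.items():
        default = getattr(SimulationParams, key)
        if isinstance(default, bool):  # pragma: no cover - no bool fields now
            pass
        if isinstance(default, int) and not isinstance(default, bool):
            if isinstance(value, bool) or not isinstance(value, int):
                raise ConfigError(f"{path}: key {key!r} must be an integer, "
                                  f"got {value!r}")
        elif isinstance(default, float):
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(f"{path}: key {key!r} must be a number, "
                                  f"got {value!r}")
            value = float(value)
        elif isinstance(default, str) and not isinstance(value, str):
            raise ConfigError(f"{path}: key {key!r} must be a string, "
                              f"got {value!r}")
        coerced[key] = value
    params = SimulationParams(**coerced)
    problems = validate(params)
    if problems:
        raise ConfigError(f"{path}: invalid configuration: "
                          + "; ".join(problems))
    return params


def read_experimental_csv(path) -> dict[str, pd.DataFrame]:
    """Read a plate-reader OD600 timeseries CSV, one series per VHR group.

    Returns ``{vhr_label: DataFrame(time, n, mean, sd)}`` sorted by time,
    suitable for side-by-side plotting with simulated host trajectories.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ConfigError(f"{path}: not a readable CSV ({exc})") from exc
    missing = [c for c in EXPERIMENTAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(
            f"{path}: missing required column(s) {missing}; expected header "
            f"{list(EXPERIMENTAL_COLUMNS)}")
    out = {}
    for label, group in df.groupby("vhr", sort=False):
        out[str(label)] = (group[["time", "n", "mean", "sd"]]
                           .sort_values("time").reset_index(drop=True))
    return out


def write_trajectory_csv(trajectory: Trajectory, path) -> None:
    """Write the tidy per-step trajectory table
    {seed, t, N_h, N_v, P_d, mean_g_alpha, mean_g_nu, mean_g_beta}."""
    trajectory.to_dataframe().to_csv(path, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    """Read a trajectory CSV back; values round-trip at full precision."""
    df = pd.read_csv(path)
    missing = [c for c in ("seed", "t", "N_h", "N_v", "P_d", "mean_g_alpha",
                           "mean_g_nu", "mean_g_beta") if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing trajectory column(s) {missing}")
    return df


def write_snapshot_csv(trajectory: Trajectory, path) -> None:
    """Companion long-format CSV of raw gene samples at snapshot times."""
    rows = []
    for t, snap in sorted(trajectory.snapshots.items()):
        for gene in ("g_alpha", "g_nu", "g_beta"):
            vals = snap[gene]
            rows.append(pd.DataFrame({
                "t": np.full(vals.size, t, dtype=np.int64),
                "gene": gene,
                "value": vals,
            }))
    table = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["t", "gene", "value"]))
    table.to_csv(path, index=False)
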