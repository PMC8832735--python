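"""File I/O and run configuration.

Streams travel as plain CSV (gzip-transparent via the ``.gz`` suffix) with
columns ``t_s``, ``pressure_cmH2O`` and a flow column whose header carries
its unit tag: ``flow_Lps`` (L/s) or ``flow_Lpm`` (L/min, converted on
read).  Transition models are JSON; recommendation and evaluation tables
are CSV.  :class:`RunConfig` collects the knobs of a full run and is
validated before anything executes; its defaults reproduce the standard
clinical grid and thresholds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .protocol import GridSpec, SafetyThresholds

__all__ = [
    "read_pressure_flow",
    "write_pressure_flow",
    "write_truth",
    "read_truth",
    "RunConfig",
    "ConfigError",
]

FLOW_UNITS = {"flow_Lps": 1.0, "flow_Lpm": 1.0 / 60.0}
REQUIRED = ("t_s", "pressure_cmH2O")


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


def read_pressure_flow(path: str | Path) -> pd.DataFrame:
    """Read and validate a pressure–flow stream CSV.

    Returns a DataFrame with canonical columns ``t_s``, ``pressure_cmH2O``,
    ``flow_Lps`` (flow normalised to L/s whatever the on-disk unit tag).
    """
    df = pd.read_csv(path)
    for col in REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    flow_cols = [c for c in df.columns if c in FLOW_UNITS]
    unknown = [c for c in df.columns if c.startswith("flow_") and c not in FLOW_UNITS]
    if unknown:
        raise ValueError(
            f"{path}: unknown flow unit tag {unknown[0]!r} "
            f"(expected one of {sorted(FLOW_UNITS)})"
        )
    if len(flow_cols) != 1:
        raise ValueError(f"{path}: expected exactly one flow column, found {flow_cols}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) == 0:
        raise ValueError(f"{path}: empty stream")
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        raise ValueError(
            f"{path}: time column not strictly increasing at row {int(bad[0]) + 1} "
            f"(t={t[bad[0]]} followed by t={t[bad[0] + 1]})"
        )
    out = pd.DataFrame(
        {
            "t_s": t,
            "pressure_cmH2O": df["pressure_cmH2O"].to_numpy(dtype=float),
            "flow_Lps": df[flow_cols[0]].to_numpy(dtype=float) * FLOW_UNITS[flow_cols[0]],
        }
    )
    return out


def write_pressure_flow(stream, path: str | Path) -> None:
    """Write a stream (dict of arrays or DataFrame) to the CSV dialect."""
    df = pd.DataFrame(stream)
    df.to_csv(path, index=False)


def write_truth(truth: dict, path: str | Path) -> None:
    """Write a virtual patient's ground-truth sidecar JSON."""
    Path(path).write_text(json.dumps(truth, indent=1))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full protocol run.

    Defaults reproduce the standard clinical grid and safety thresholds,
    so a bare config recommends against the full 189,000-combination grid.
    """

    config_version: int = 1
    grid: GridSpec = field(default_factory=GridSpec)
    thresholds: SafetyThresholds = field(default_factory=SafetyThresholds)
    interval_len: float = 600.0
    horizon: float = 10800.0
    bandwidth_rule: str = "silverman"
    objective: str = "min_dP"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.config_version != 1:
            raise ConfigError(f"unsupported config_version {self.config_version}")
        if self.interval_len <= 0 or self.horizon <= 0:
            raise ConfigError("interval_len and horizon must be positive")
        if self.objective != "min_dP":
            raise ConfigError(f"unknown objective {self.objective!r}")
        if isinstance(self.bandwidth_rule, str) and self.bandwidth_rule not in (
            "silverman",
            "scott",
        ):
            raise ConfigError(f"unknown bandwidth rule {self.bandwidth_rule!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")
        try:
            self.grid.axes()
        except ValueError as exc:
            raise ConfigError(f"invalid grid: {exc}") from exc

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        if "grid" in d and isinstance(d["grid"], dict):
            g = {k: tuple(v) if isinstance(v, list) else v for k, v in d["grid"].items()}
            d["grid"] = GridSpec(**g)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            t = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["thresholds"].items()
            }
            d["thresholds"] = SafetyThresholds(**t)
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)
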