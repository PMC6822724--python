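"""Run configuration: validated YAML/inline configs and result serialization.

A :class:`RunConfig` names the experiment to run plus the physical and
numerical settings, all in documented units (seconds, Hz, ms as the field
names say).  Unknown keys are rejected and every run writes a JSON
manifest (config echo, package version, timestamp) next to its tables so
a run is reconstructible from its outputs.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigError


class RunConfig(BaseModel):
    """Validated configuration for one simulation run."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    experiment: Literal["exp1", "exp2_solo", "exp2_duet", "exp3", "sweep", "classify"]
    profile: Literal["musician", "nonmusician"] = "musician"
    feedback: Literal["on", "off"] = "on"
    ioi_list_ms: Sequence[float] = (
        1000, 1250, 1500, 1750, 2000, 2250, 2500, 2750, 3000, 3250, 3500,
    )
    duration_s: Optional[float] = Field(default=None, gt=0)
    dt_s: float = Field(default=1e-3, gt=0)
    n_cycles: int = Field(default=16, ge=8)
    tl_list_ms: Sequence[float] = (0.0, 10.0, 20.0, 39.0, 58.0, 78.0)
    delta_hz: float = 0.0
    # Sweep / classification settings.
    A: float = -0.5
    f_hz: float = Field(default=1.0, gt=0)
    D: float = Field(default=1.0, ge=0)
    tau_s: float = Field(default=0.222, ge=0)
    D_grid: Optional[Sequence[float]] = None
    tau_grid_s: Optional[Sequence[float]] = None
    normalize: bool = True
    out: Optional[str] = None
    trajectory_out: Optional[str] = None
    verbosity: int = Field(default=0, ge=0, le=2)
    # All dynamics are deterministic; the seed is echoed into manifests so
    # batch tooling can treat runs uniformly.
    seed: int = Field(default=0, ge=0)

    @field_validator("ioi_list_ms", "tl_list_ms")
    @classmethod
    def _positive_entries(cls, v, info):
        for x in v:
            if x < 0 or (info.field_name == "ioi_list_ms" and x <= 0):
                raise ValueError(f"{info.field_name} entries must be positive, got {x}")
        return tuple(float(x) for x in v)

    @field_validator("tl_list_ms")
    @classmethod
    def _tl_range(cls, v):
        for x in v:
            if x > 1000.0:
                raise ValueError(f"transmission latency {x} ms is out of range")
        return v


def load_config(source) -> RunConfig:
    """Build a validated RunConfig from a YAML file path or an inline mapping."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
    elif isinstance(source, dict):
        data = source
    else:
        raise ConfigError(f"cannot load a config from {type(source).__name__}")
    try:
        return RunConfig(**data)
    except ValidationError as err:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc']) or '<root>'}: {e['msg']}"
            for e in err.errors()
        )
        raise ConfigError(f"invalid configuration: {details}") from err


def serialize_config(config: RunConfig) -> dict:
    """Plain-dict form of a config; load_config(serialize_config(c)) == c."""
    return json.loads(config.model_dump_json())


def write_results(
    tables: dict[str, pd.DataFrame],
    out_path,
    config: RunConfig | None = None,
    trajectories: dict[str, pd.DataFrame] | None = None,
) -> list[Path]:
    """Write result tables as CSV plus a JSON run manifest.

    ``tables`` maps a suffix (empty string for the primary table) to a
    DataFrame.  The manifest echoes the config and records the package
    version and timestamp.  Fails before writing anything if the output
    directory is not writable.
    """
    from . import __version__

    out_path = Path(out_path)
    directory = out_path.parent if out_path.parent != Path("") else Path(".")
    directory.mkdir(parents=True, exist_ok=True)
    probe = directory / f".write_probe_{out_path.name}"
    try:
        probe.touch()
        probe.unlink()
    except OSError as err:
        raise ConfigError(f"output directory {directory} is not writable: {err}") from err

    written: list[Path] = []
    for suffix, table in tables.items():
        path = out_path if not suffix else out_path.with_name(
            out_path.stem + f"_{suffix}" + out_path.suffix
        )
        table.to_csv(path, index=False)
        written.append(path)
    for name, frame in (trajectories or {}).items():
        path = out_path.with_name(out_path.stem + f"_{name}.csv")
        frame.to_csv(path, index=False)
        written.append(path)

    manifest = {
        "config": serialize_config(config) if config is not None else None,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": [str(p) for p in written],
    }
    manifest_path = out_path.with_suffix(".manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    written.append(manifest_path)
    return written
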