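"""CSV / YAML / JSON interchange and run manifests."""

from __future__ import annotations

import csv
import dataclasses
import datetime
import json
import pathlib
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigError, FormatError
from .inference import GAConfig
from .kernel import MCSModel, ReleaseCurve, SimulationConfig

__all__ = [
    "load_release_csv",
    "save_release_csv",
    "load_sim_config",
    "load_ga_config",
    "RunManifest",
]

_VALUE_COLUMNS = ("remaining", "fraction")


def load_release_csv(path, n0: Optional[float] = None) -> ReleaseCurve:
    """Read a two-column release curve (``time,remaining`` or ``time,fraction``).

    Times must be strictly increasing and values non-negative; fractional
    values must lie in [0, 1].  A fractional curve is converted to remaining
    amounts when ``n0`` is supplied, otherwise kept as a fraction curve.
    Format errors name the offending row.
    """
    path = pathlib.Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError("empty file") from None
        header = [h.strip() for h in header]
        if len(header) < 2 or header[0] != "time" or header[1] not in _VALUE_COLUMNS:
            raise FormatError(
                f"expected header 'time,remaining' or 'time,fraction', got {header}"
            )
        kind = header[1]
        times, values = [], []
        for i, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                t, v = float(row[0]), float(row[1])
            except (ValueError, IndexError):
                raise FormatError(f"could not parse {row!r}", row=i) from None
            if times and t <= times[-1]:
                raise FormatError(f"time {t} not strictly increasing", row=i)
            if v < 0:
                raise FormatError(f"negative value {v}", row=i)
            if kind == "fraction" and v > 1.0:
                raise FormatError(f"fraction {v} outside [0, 1]", row=i)
            times.append(t)
            values.append(v)
    if not times:
        raise FormatError("no data rows")
    t = np.array(times)
    v = np.array(values)
    if kind == "fraction":
        if n0 is not None:
            return ReleaseCurve(t, n0 * (1.0 - v), n0=float(n0),
                                meta={"kind": "remaining", "source": str(path)})
        return ReleaseCurve(t, v, n0=1.0,
                            meta={"kind": "fraction", "source": str(path)})
    return ReleaseCurve(t, v, n0=float(n0) if n0 is not None else float(v[0]),
                        meta={"kind": "remaining", "source": str(path)})


def save_release_csv(curve: ReleaseCurve, path, include_fraction: bool = False) -> None:
    """Write a curve as CSV ('.' decimal, comma separator, mandatory header)."""
    path = pathlib.Path(path)
    value_col = "fraction" if curve.kind == "fraction" else "remaining"
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        if include_fraction and curve.kind == "remaining":
            writer.writerow(["time", value_col, "fraction"])
            for t, v, f in zip(curve.t, curve.N, curve.fraction_values()):
                writer.writerow([repr(float(t)), repr(float(v)), repr(float(f))])
        else:
            writer.writerow(["time", value_col])
            for t, v in zip(curve.t, curve.N):
                writer.writerow([repr(float(t)), repr(float(v))])


# ---------------------------------------------------------------------------
# YAML configs


def _check_keys(data: dict, cls, what: str) -> None:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown {what} key(s): {sorted(unknown)}")


def _load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    return data


def sim_config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    mcs_data = data.pop("mcs", None)
    _check_keys(data, SimulationConfig, "simulation config")
    if mcs_data is not None:
        _check_keys(mcs_data, MCSModel, "mcs model")
        data["mcs"] = MCSModel(**mcs_data)
    return SimulationConfig(**data)


def load_sim_config(path) -> SimulationConfig:
    return sim_config_from_dict(_load_yaml(path))


def ga_config_from_dict(data: dict) -> GAConfig:
    data = dict(data)
    _check_keys(data, GAConfig, "GA config")
    if "bounds" in data:
        data["bounds"] = {k: tuple(v) for k, v in data["bounds"].items()}
    if "time_scale_bounds" in data:
        data["time_scale_bounds"] = tuple(data["time_scale_bounds"])
    return GAConfig(**data)


def load_ga_config(path) -> GAConfig:
    return ga_config_from_dict(_load_yaml(path))


# ---------------------------------------------------------------------------
# manifests


@dataclasses.dataclass
class RunManifest:
    """Provenance record written alongside every CLI output."""

    command: str
    config: dict
    seed: Optional[int]
    outputs: list
    package_version: str
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonable)
            fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def config_snapshot(obj) -> dict:
    """A JSON-safe dict snapshot of a (possibly nested) dataclass config."""
    if dataclasses.is_dataclass(obj):
        return json.loads(json.dumps(dataclasses.asdict(obj), default=_jsonable))
    return json.loads(json.dumps(obj, default=_jsonable))
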