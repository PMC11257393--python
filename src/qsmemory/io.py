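"""Config handling, run logs and structured result writers."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import KineticParameters, AnalyticalParams

__all__ = ["RunConfig", "load_config", "config_hash", "RunLog"]


@dataclass(frozen=True)
class RunConfig:
    """A fully serializable description of one pipeline run."""

    params: KineticParameters
    analytical: AnalyticalParams
    scenarios: tuple = ()
    out_dir: str = "results"
    rtol: float = 1e-8
    atol: float = 1e-10
    grid_points_per_decade: int = 41
    resolution: float = 0.01
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "analytical": self.analytical.to_dict(),
            "scenarios": list(self.scenarios),
            "out_dir": self.out_dir,
            "rtol": self.rtol,
            "atol": self.atol,
            "grid_points_per_decade": self.grid_points_per_decade,
            "resolution": self.resolution,
            "seed": self.seed,
            "extra": self.extra,
        }

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(data: dict) -> str:
    """Short stable digest of a config mapping."""
    blob = json.dumps(data, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Read a YAML/JSON run config; missing sections fall back to defaults.

    Recognised top-level keys: ``params`` (Table-1 symbols), ``analytical``,
    ``scenarios``, ``out_dir``, ``rtol``, ``atol``,
    ``grid_points_per_decade``, ``resolution``, ``seed``.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text)) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} did not parse to a mapping")
    data.update(overrides)
    try:
        params = KineticParameters.from_dict(data.get("params", {}) or {})
    except (KeyError, ValueError, TypeError) as err:
        raise ValueError(f"invalid 'params' section: {err}") from err
    try:
        analytical = AnalyticalParams.from_dict(data.get("analytical", {}) or {})
    except (KeyError, ValueError, TypeError) as err:
        raise ValueError(f"invalid 'analytical' section: {err}") from err
    known = {"params", "analytical", "scenarios", "out_dir", "rtol", "atol",
             "grid_points_per_decade", "resolution", "seed"}
    extra = {k: v for k, v in data.items() if k not in known}
    return RunConfig(
        params=params,
        analytical=analytical,
        scenarios=tuple(data.get("scenarios", ()) or ()),
        out_dir=str(data.get("out_dir", "results")),
        rtol=float(data.get("rtol", 1e-8)),
        atol=float(data.get("atol", 1e-10)),
        grid_points_per_decade=int(data.get("grid_points_per_decade", 41)),
        resolution=float(data.get("resolution", 0.01)),
        seed=int(data.get("seed", 0)),
        extra=extra,
    )


class RunLog:
    """Append-only JSON-lines run log."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def append(self, record: dict) -> None:
        record = dict(record)
        record.setdefault("timestamp", time.strftime("%Y-%m-%dT%H:%M:%S"))
        with self.path.open("a") as fh:
            fh.write(json.dumps(record, default=str) + "\n")

    def records(self) -> list[dict]:
        if not self.path.exists():
            return []
        return [json.loads(line) for line in self.path.read_text().splitlines() if line]
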