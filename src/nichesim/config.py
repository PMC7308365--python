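"""Run configuration, validation and reproducibility manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .params import ModelParams

__all__ = ["RunConfig", "load_config", "write_manifest", "load_manifest"]

_MODEL_KEYS = {
    "delta",
    "e",
    "c",
    "alpha",
    "r_col",
    "r_con",
    "global_construction",
    "competition",
}
_PROTOCOL_KEYS = {
    "L",
    "t_transient",
    "t_avg",
    "t_max",
    "sample_dt",
    "replicates",
}
_TOP_KEYS = {"model", "protocol", "seed", "outdir"}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a simulation or experiment run.

    Defaults follow the reference protocol: 256 x 256 lattice, 5000 time
    units of transient, 250 units of averaging, nearest-neighbor
    colonization.  Unknown keys in a config file are rejected outright.
    """

    params: ModelParams = field(default_factory=lambda: ModelParams(delta=0.1))
    L: int = 256
    t_transient: float = 5000.0
    t_avg: float = 250.0
    t_max: float = 5250.0
    sample_dt: float = 1.0
    replicates: int = 1
    seed: int = 0
    outdir: str = "nichesim-out"

    def __post_init__(self) -> None:
        if self.L < 4:
            raise ValueError(f"L must be >= 4, got {self.L}")
        for name in ("t_transient", "t_avg", "t_max", "sample_dt"):
            if getattr(self, name) <= 0 and name != "t_transient":
                raise ValueError(f"{name} must be positive")
        if self.t_transient < 0:
            raise ValueError("t_transient must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        return d


def _reject_unknown(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


def config_from_dict(data: dict) -> RunConfig:
    _reject_unknown(data, _TOP_KEYS, "config")
    model = dict(data.get("model", {}))
    _reject_unknown(model, _MODEL_KEYS, "config section 'model'")
    protocol = dict(data.get("protocol", {}))
    _reject_unknown(protocol, _PROTOCOL_KEYS, "config section 'protocol'")
    model.setdefault("delta", 0.1)
    params = ModelParams(**model)
    kwargs: dict = dict(protocol)
    if "t_max" not in kwargs:
        t_tr = kwargs.get("t_transient", 5000.0)
        t_av = kwargs.get("t_avg", 250.0)
        kwargs["t_max"] = t_tr + t_av
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "outdir" in data:
        kwargs["outdir"] = str(data["outdir"])
    return RunConfig(params=params, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML or YAML config file.

    The file may contain ``[model]`` and ``[protocol]`` sections plus
    top-level ``seed`` and ``outdir``; omitted fields take the reference
    defaults.  Unknown keys raise a field-level error.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text) or {}
    else:
        import tomllib

        data = tomllib.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"config root in {path} must be a mapping")
    return config_from_dict(data)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    config: RunConfig,
    results: dict,
    path: str | Path,
    outputs: list[str | Path] | None = None,
    complete: bool = True,
    elapsed_seconds: float | None = None,
) -> dict:
    """Write a JSON reproducibility manifest next to a run's outputs.

    Records the full configuration (params + seed), a results summary
    (e.g. event tallies, final occupancies), wall-clock timing, the output
    file list with SHA-256 checksums, and whether the run completed.
    """
    path = Path(path)
    manifest = {
        "config": config.to_dict(),
        "results": results,
        "complete": bool(complete),
        "elapsed_seconds": elapsed_seconds,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": [
            {"path": str(p), "sha256": _checksum(Path(p))}
            for p in (outputs or [])
            if Path(p).exists()
        ],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
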