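"""Run configuration and result serialization.

A :class:`RunConfig` gathers every tunable of the package — model parameter
blocks, solver tolerances, grids and the random seed — with literature
defaults throughout.  Configurations load from YAML or JSON, merged over
the defaults with strict unknown-key rejection, and every result file
written through :func:`write_results` embeds the effective-config hash and
seed so outputs are regenerable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import SolverConfig
from .endocrine import EndocrineParams
from .errors import ConfigError
from .scenario import PrevalenceInputs
from .steroid import SteroidMapParams
from .thalamo import ThalamoParams

__all__ = ["RunConfig", "load_config", "config_hash", "write_results"]


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of a run: parameter blocks + solver + seed."""

    thalamo: ThalamoParams = field(default_factory=ThalamoParams)
    steroid: SteroidMapParams = field(default_factory=SteroidMapParams)
    endocrine: EndocrineParams = field(default_factory=EndocrineParams)
    prevalence: PrevalenceInputs = field(default_factory=PrevalenceInputs)
    solver: SolverConfig = field(default_factory=SolverConfig)
    seed: int = 0
    outdir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_BLOCKS = {
    "thalamo": ThalamoParams,
    "steroid": SteroidMapParams,
    "endocrine": EndocrineParams,
    "prevalence": PrevalenceInputs,
    "solver": SolverConfig,
}


def _build_block(name: str, cls, overrides: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) in block {name!r}: {', '.join(sorted(unknown))}; "
            f"valid keys: {', '.join(sorted(valid))}"
        )
    for k, v in overrides.items():
        if not isinstance(v, (int, float, str, bool)):
            raise ConfigError(f"{name}.{k}: expected a scalar, got {type(v).__name__}")
    try:
        return cls(**overrides)
    except Exception as exc:  # surface parameter-range violations with the key
        raise ConfigError(f"invalid value in block {name!r}: {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML/JSON config file merged over the defaults.

    An empty (or absent) file yields all defaults; unknown blocks or keys
    raise :class:`ConfigError` naming the offender.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")

    unknown = set(raw) - set(_BLOCKS) - {"seed", "outdir"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")

    kwargs: dict = {}
    for name, cls in _BLOCKS.items():
        block = raw.get(name, {})
        if not isinstance(block, dict):
            raise ConfigError(f"block {name!r} must be a mapping")
        kwargs[name] = _build_block(name, cls, block)
    if "seed" in raw:
        if not isinstance(raw["seed"], int):
            raise ConfigError("seed must be an integer")
        kwargs["seed"] = raw["seed"]
    if "outdir" in raw:
        kwargs["outdir"] = str(raw["outdir"])
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the effective configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _jsonify(obj):
    if hasattr(obj, "to_dict"):
        return _jsonify(obj.to_dict())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, complex):
        return [obj.real, obj.imag]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_results(
    obj, path: str | Path, config: RunConfig | None = None
) -> Path:
    """Serialize a result to disk: CSV for tabular data, JSON otherwise.

    DataFrames (and objects exposing ``to_frame``) go to CSV with a
    ``# config=<hash> seed=<n>`` comment header; everything else is written
    as a JSON document with ``config_hash`` and ``seed`` fields alongside
    the payload.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = config or RunConfig()
    meta = f"config={config_hash(cfg)} seed={cfg.seed}"
    if hasattr(obj, "to_frame"):
        obj = obj.to_frame()
    if isinstance(obj, pd.DataFrame):
        with open(path, "w") as fh:
            fh.write(f"# {meta}\n")
            obj.to_csv(fh, index=False)
    else:
        doc = {"config_hash": config_hash(cfg), "seed": cfg.seed,
               "result": _jsonify(obj)}
        path.write_text(json.dumps(doc, indent=2) + "\n")
    return path
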