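"""Run configuration: parsing, validation, scorer construction, snapshots."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .conformation import read_pdb
from .eda import EdaConfig
from .energy import OracleScore, ReferenceScore, ScoreFunction
from .sampler import SamplerConfig

__all__ = ["ScorerConfig", "RunConfig", "load_run_config", "make_score", "resolved_dict"]


@dataclass
class ScorerConfig:
    name: str = "reference"  # "reference" (native-blind) or "oracle"
    w_clash: float = 1.0
    w_rg: float = 1.0
    w_contact: float = 1.0
    oracle_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ("reference", "oracle"):
            raise ValueError(f"unknown scorer '{self.name}'")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run (written back as a snapshot)."""

    sequence: str = "target.fasta"
    fragments9: str = "frags9.txt"
    fragments3: str = "frags3.txt"
    native: str | None = None
    outdir: str = "run"
    eda: EdaConfig = field(default_factory=EdaConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    scorer: ScorerConfig = field(default_factory=ScorerConfig)
    seed: int = 0
    workers: int = 1
    write_pdbs: bool = True

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.scorer.name == "oracle" and not self.native:
            raise ValueError("the oracle scorer requires a native structure path")


def _build(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {context} config field(s): {sorted(unknown)}")
    return cls(**data)


def load_run_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    for key, cls in (("eda", EdaConfig), ("sampler", SamplerConfig), ("scorer", ScorerConfig)):
        if key in data:
            data[key] = _build(cls, dict(data[key]), key)
    return _build(RunConfig, data, "run")


def resolved_dict(config: RunConfig) -> dict:
    return asdict(config)


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(resolved_dict(config), sort_keys=False))


def make_score(config: ScorerConfig, native=None) -> ScoreFunction:
    """Instantiate the configured score function."""
    if config.name == "reference":
        return ReferenceScore(
            w_clash=config.w_clash, w_rg=config.w_rg, w_contact=config.w_contact
        )
    if native is None:
        raise ValueError("oracle scorer needs native coordinates")
    if isinstance(native, (str, Path)):
        _, native = read_pdb(native)
    return OracleScore(native_ca=native, sigma=config.oracle_sigma)


def _json_default(obj):
    import numpy as np

    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def dump_json(data, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_json_default) + "\n")
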