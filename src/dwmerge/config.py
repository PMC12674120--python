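"""Run configuration: YAML schema shared by all CLI subcommands.

Top-level keys (all optional unless a subcommand needs them):

.. code-block:: yaml

    seed: 0
    output_dir: out
    data:
      tables: [observations.csv]     # delimited reflection tables
      dialect: csv
    graph:
      nodes: [apo, holo]
      edges:
        holo: {parent: apo, r: 0.99}
    features:
      metadata_columns: [det_x, det_y, wavelength]
      positional_encoding_columns: [det_x, det_y]
      n_frequencies: 8
    training:
      steps: 2000
      learning_rate: 1.0e-3
      n_samples: 8
      r_mode: fixed
      likelihood: normal
    scan: {n_points: 15, subset_fraction: 1.0}
    simulate: {...SimulationConfig fields...}
    diff: {child: holo, parent: apo, alpha: 0.0}

The resolved configuration is written beside every run's outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import ConfigError
from .refl_io import DatasetGraph, ReflectionTable, read_reflection_table
from .scaling import FeatureSpec, MLPConfig
from .simulate import SimulationConfig
from .vi import TrainingConfig

__all__ = ["RunConfig", "load_config"]


def _build(cls, d: dict, what: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigError(f"unknown {what} field(s): {sorted(unknown)}")
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    try:
        return cls(**coerced)
    except TypeError as exc:
        raise ConfigError(f"bad {what} block: {exc}") from exc


@dataclass
class RunConfig:
    """Schema-validated view over a YAML run configuration."""

    raw: dict
    path: Path

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def output_dir(self) -> Path:
        return Path(self.raw.get("output_dir", "dwmerge_out"))

    def subseed(self, name: str) -> int:
        """Fan the master seed out into independent named streams."""
        import zlib
        return (self.seed * 1_000_003 + zlib.crc32(name.encode())) % (2 ** 31)

    def training(self) -> TrainingConfig:
        block = dict(self.raw.get("training", {}))
        feat = self.features()
        mlp = _build(MLPConfig, dict(self.raw.get("mlp", {})), "mlp")
        block.setdefault("seed", self.seed)
        cfg = _build(TrainingConfig, block, "training")
        return dataclasses.replace(cfg, features=feat, mlp=mlp)

    def features(self) -> FeatureSpec:
        return _build(FeatureSpec, dict(self.raw.get("features", {})), "features")

    def simulation(self) -> SimulationConfig:
        block = dict(self.raw.get("simulate", {}))
        if "graph" in self.raw and "nodes" not in block:
            g = self.graph()
            block["nodes"] = tuple(g.nodes)
            block["edges"] = tuple((e.parent, e.child, e.r) for e in g.edges)
        block.setdefault("seed", self.seed)
        cfg = _build(SimulationConfig, block, "simulate")
        return cfg.validate()

    def graph(self) -> DatasetGraph:
        if "graph" not in self.raw:
            raise ConfigError("missing 'graph' block")
        try:
            return DatasetGraph.from_dict(self.raw["graph"])
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"bad graph block: {exc}") from exc

    def tables(self) -> ReflectionTable:
        data = self.raw.get("data") or {}
        paths = data.get("tables")
        if not paths:
            raise ConfigError("missing 'data.tables' list")
        dialect = data.get("dialect", "csv")
        frames = []
        base = self.path.parent
        for p in paths:
            p = Path(p)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"input table not found: {p}")
            frames.append(read_reflection_table(p, dialect).data)
        return ReflectionTable.from_frame(pd.concat(frames, ignore_index=True))

    def write_resolved(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=False)


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    return RunConfig(raw, path)
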