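"""Run configuration: one nested, fully-defaulted config object for the pipeline.

Every key has a default; unknown keys in a config file are rejected rather
than ignored, and the effective configuration is serialized alongside every
output directory so runs are auditable and reproducible from one global
seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PreprocessConfig:
    target_fs: float = 500.0
    band: tuple[float, float] = (0.1, 30.0)
    win_ms: float = 250.0
    overlap_ms: float = 125.0
    bad_k: float = 5.0
    flat_eps: float = 1e-12
    car: bool = False  # common-average re-reference (off: as-recorded montage)


@dataclass
class DynamicsConfig:
    reg: float = 0.05


@dataclass
class FragilityConfig:
    mode: str = "column"
    omega_points: int = 51


@dataclass
class ClassifierConfig:
    n_trees: int = 500
    threshold: float = 0.5


@dataclass
class RunConfig:
    """Merged configuration of all pipeline stages plus the global seed.

    The single ``seed`` fans out deterministically to every stochastic
    stage (simulation, forest training), so fixing it makes reruns
    bit-identical.
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    fragility: FragilityConfig = field(default_factory=FragilityConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        sections = {f.name: f for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key == "seed":
                cfg.seed = int(value)
                continue
            if key not in sections or key == "seed":
                raise ValueError(f"unknown config section {key!r}")
            section = getattr(cfg, key)
            valid = {f.name for f in dataclasses.fields(section)}
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            for k, v in value.items():
                if k not in valid:
                    raise ValueError(f"unknown config key {key}.{k}")
                if k == "band":
                    v = tuple(float(x) for x in v)
                setattr(section, k, v)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        elif path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(text)
        else:
            raise ValueError(f"unsupported config format {path.suffix!r} (use YAML or TOML)")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=list)
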