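"""Run configuration: YAML file + CLI overrides, with unknown keys rejected."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import __version__
from .errors import ParameterError


@dataclass
class AnalyzeConfig:
    eye: str = "left"
    vel_thresh: float = 30.0
    acc_thresh: float = 8000.0
    min_consecutive: int = 2
    continuation_window_ms: float = 20.0
    post_blink_discard_ms: float = 50.0
    merge_gap_ms: float = 100.0
    trim_start_ms: float = 6.0
    trim_end_ms: float = 4.0
    min_duration_ms: float = 50.0
    m_max: int = 100
    peak_window_ms: float = 30.0
    jitter_px: float = 0.05
    middle_window_ms: float = 50.0
    tail_xmin_px: float = 0.1
    microsaccade_lambda: float = 5.0
    microsaccade_min_duration_ms: float = 6.0
    saccade_exclusion_ms: float = 30.0
    n_surrogates: int = 10


@dataclass
class SimulateConfig:
    tau: int = 10
    sigma: float = 1.0
    alpha: float = 1.0
    n_walks: int = 100
    n_steps: int = 500
    m_max: int = 100
    grid_size: int = 1024


@dataclass
class TableConfig:
    preset: str = "coarse"       # coarse | full
    dt_max_ms: float = 20.0


@dataclass
class SynthConfig:
    fixtures: tuple = ("clean", "blinky", "microsaccade_rich", "ballistic_drift", "diffusive_drift")


@dataclass
class RunConfig:
    seed: int = 0
    analyze: AnalyzeConfig = field(default_factory=AnalyzeConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    table: TableConfig = field(default_factory=TableConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config section(s): {sorted(unknown)}")
        for name, value in data.items():
            if name == "seed":
                cfg.seed = int(value)
                continue
            section = getattr(cfg, name)
            sec_known = {f.name for f in fields(section)}
            bad = set(value) - sec_known
            if bad:
                raise ParameterError(f"unknown key(s) in [{name}]: {sorted(bad)}")
            for k, v in value.items():
                setattr(section, k, v)
        return cfg

    def resolved(self) -> dict:
        out = asdict(self)
        out["synth"]["fixtures"] = list(out["synth"]["fixtures"])
        return out

    def write_manifest(self, out_dir, command: str, extra: dict | None = None) -> None:
        manifest = {
            "command": command,
            "version": __version__,
            "seed": self.seed,
            "config": self.resolved(),
        }
        if extra:
            manifest.update(extra)
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        (Path(out_dir) / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
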