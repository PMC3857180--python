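"""Typed pipeline configuration with strict YAML (de)serialization.

Unknown keys are rejected so typos in a config file fail loudly instead of
silently falling back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .preprocess import PreprocessParams
from .segmentation import LevelSetParams
from .spotdetect import DetectParams

__all__ = ["BinaryParams", "StatsParams", "EvalParams", "PipelineConfig"]


@dataclass
class BinaryParams:
    disk_radius_px: int = 2
    min_area_px: int = 200
    h_merge: float = 4.0

    def validate(self) -> None:
        if self.disk_radius_px < 0 or self.min_area_px < 0 or self.h_merge < 0:
            raise ValueError("binary-enhancement parameters must be >= 0")


@dataclass
class StatsParams:
    alpha: float = 0.001
    null_multiplier: int = 10
    lower_cut: float = 0.95
    smoothing_window: int = 3

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.null_multiplier < 1:
            raise ValueError("null_multiplier must be >= 1")
        if not (0 < self.lower_cut < 1):
            raise ValueError("lower_cut must be in (0, 1)")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")


@dataclass
class EvalParams:
    match_tolerance_px: float | None = None  # None -> detect.r2

    def validate(self) -> None:
        if self.match_tolerance_px is not None and self.match_tolerance_px <= 0:
            raise ValueError("match_tolerance_px must be > 0")


@dataclass
class PipelineConfig:
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    levelset: LevelSetParams = field(default_factory=LevelSetParams)
    binary: BinaryParams = field(default_factory=BinaryParams)
    detect: DetectParams = field(default_factory=DetectParams)
    stats: StatsParams = field(default_factory=StatsParams)
    eval: EvalParams = field(default_factory=EvalParams)
    resize_factor: float = 1.0
    seed: int = 0

    _SECTIONS = ("preprocess", "levelset", "binary", "detect", "stats", "eval")

    def validate(self) -> None:
        if not (0 < self.resize_factor <= 1):
            raise ValueError("resize_factor must be in (0, 1]")
        for name in self._SECTIONS:
            getattr(self, name).validate()

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {name: asdict(getattr(self, name)) for name in self._SECTIONS}
        d["preprocess"]["clahe_tiles"] = list(self.preprocess.clahe_tiles)
        d["resize_factor"] = self.resize_factor
        d["seed"] = self.seed
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        section_types = {"preprocess": PreprocessParams, "levelset": LevelSetParams,
                         "binary": BinaryParams, "detect": DetectParams,
                         "stats": StatsParams, "eval": EvalParams}
        for name, typ in section_types.items():
            sub = dict(d.pop(name, {}))
            valid = set(typ.__dataclass_fields__)
            unknown = set(sub) - valid
            if unknown:
                raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
            if name == "preprocess" and "clahe_tiles" in sub:
                sub["clahe_tiles"] = tuple(sub["clahe_tiles"])
            kwargs[name] = typ(**sub)
        for key in ("resize_factor", "seed"):
            if key in d:
                kwargs[key] = d.pop(key)
        if d:
            raise ValueError(f"unknown top-level config keys: {sorted(d)}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)
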