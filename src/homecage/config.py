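"""Run-level configuration: one YAML/JSON file covering every stage.

Unknown keys are rejected so a typo in a config file fails loudly
instead of silently running with defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .motion import MotionConfig
from .scoring import EmgScoringConfig, LfpScoringConfig, VideoScoringConfig
from .tracking import TrackingConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    motion: MotionConfig = field(default_factory=MotionConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    video_scoring: VideoScoringConfig = field(default_factory=VideoScoringConfig)
    emg_scoring: EmgScoringConfig = field(default_factory=EmgScoringConfig)
    lfp_scoring: LfpScoringConfig = field(default_factory=LfpScoringConfig)
    fps: float = 15.0
    ephys_fs: float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        sub = {
            "motion": MotionConfig,
            "tracking": TrackingConfig,
            "video_scoring": VideoScoringConfig,
            "emg_scoring": EmgScoringConfig,
            "lfp_scoring": LfpScoringConfig,
        }
        for key, klass in sub.items():
            if key in data:
                kwargs[key] = _build(klass, data.pop(key), where=key)
        for key in ("fps", "ephys_fs", "seed"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ValueError(f"unknown config keys: {sorted(data)}")
        return cls(**kwargs)


def _build(klass, data: dict, where: str):
    allowed = {f.name for f in dataclasses.fields(klass)}
    data = dict(data or {})
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in '{where}': {sorted(unknown)}")
    for f in dataclasses.fields(klass):
        # YAML lists stand in for tuples
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    return klass(**data)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def load_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return RunConfig.from_dict(data or {})
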