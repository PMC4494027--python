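"""Structured pipeline configuration with lossless YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from blockmvpa.errors import ConfigError


@dataclass
class DesignSection:
    tr_s: float = 2.5
    block_s: float = 10.0
    fix_s: float = 7.5
    initial_fix_s: float = 10.0
    blocks_per_cond: int = 6
    word_s: float = 0.4
    words_per_sentence: int = 6
    sentences_per_block: int = 4
    conditions: list[str] = field(default_factory=lambda: ["sentences", "nonwords"])
    n_main_sessions: int = 8
    n_localizer_sessions: int = 4


@dataclass
class SignalSection:
    baseline: float = 100.0
    pattern_amplitude: float = 0.0  # per-voxel pattern difference strength
    global_offset: float = 0.0  # condition-level scalar offset difference
    localizer_amplitude: float = 3.0  # selective response in language parcels
    localizer_gain: float = 1.0
    signal_regions: list[str] = field(
        default_factory=lambda: ["L_PosteriorSTS", "L_MiddleFrontalGyrus"]
    )


@dataclass
class NoiseSection:
    white_sd: float = 1.0
    ar1: float = 0.3
    drift_amplitude: float = 0.5
    drift_period_s: float = 128.0


@dataclass
class AwarenessSection:
    p_guessed: dict = field(
        default_factory=lambda: {"sentences": 0.803, "nonwords": 0.826}
    )
    p_correct_given_guessed: float = 0.517
    p_correct_given_knew: dict = field(
        default_factory=lambda: {"sentences": 0.624, "nonwords": 0.865}
    )


@dataclass
class PreprocSection:
    discard_volumes: int = 4
    smoothing_fwhm_mm: float = 6.0
    smooth_main: bool = False  # smoothing of main-experiment runs is optional
    lag_trs: int = 3


@dataclass
class RoiSection:
    sizes: list[int] = field(default_factory=lambda: [100])
    connectivity: int = 26
    mask_seed: int = 1234


@dataclass
class ClassifierSection:
    C: float = 1.0


@dataclass
class StatsSection:
    family_alpha: float = 0.05
    chance: float = 50.0


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs; master seed is mandatory."""

    seed: int
    n_subjects: int = 15
    grid_shape: list[int] = field(default_factory=lambda: [12, 12, 8])
    voxel_size_mm: list[float] = field(default_factory=lambda: [2.0, 2.0, 3.0])
    out_dir: str = "results"
    design: DesignSection = field(default_factory=DesignSection)
    signal: SignalSection = field(default_factory=SignalSection)
    noise: NoiseSection = field(default_factory=NoiseSection)
    awareness: AwarenessSection = field(default_factory=AwarenessSection)
    preproc: PreprocSection = field(default_factory=PreprocSection)
    roi: RoiSection = field(default_factory=RoiSection)
    classifier: ClassifierSection = field(default_factory=ClassifierSection)
    stats: StatsSection = field(default_factory=StatsSection)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a master seed is mandatory")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "seed" not in d:
            raise ConfigError("config is missing the mandatory 'seed'")
        sections = {
            "design": DesignSection,
            "signal": SignalSection,
            "noise": NoiseSection,
            "awareness": AwarenessSection,
            "preproc": PreprocSection,
            "roi": RoiSection,
            "classifier": ClassifierSection,
            "stats": StatsSection,
        }
        for key, klass in sections.items():
            if key in d and isinstance(d[key], dict):
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(d[key]) - known
                if unknown:
                    raise ConfigError(f"unknown {key} option(s): {sorted(unknown)}")
                d[key] = klass(**d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config option(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
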