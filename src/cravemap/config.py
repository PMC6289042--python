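"""Pipeline configuration: one dataclass tree, YAML (de)serialization, defaults.

The top-level block fixes the study design constants (five runs of 36 trials,
TR 2 s, 380 frames per run); each analysis stage owns a nested block with its
numeric parameters.  ``from_yaml`` fills any omitted key with its default so a
partial config file is always valid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class GlmConfig:
    highpass_hz: float = 1.0 / 128.0
    smooth_fwhm_mm: float = 8.0
    hrf_dt: float = 0.1          # oversampling step for HRF convolution (s)
    rating_duration_s: float = 3.0


@dataclass
class MvpaConfig:
    radius_voxels: int = 3
    svc_c: float = 1.0
    n_perm_chance: int = 100
    min_sphere_voxels: int = 10


@dataclass
class NbsConfig:
    n_rois: int = 116
    link_alpha: float = 0.001
    n_perm: int = 1000
    alpha: float = 0.05
    fdr_q: float = 0.001
    base_r: float = 0.2


@dataclass
class GroupConfig:
    alpha: float = 0.05
    n_perm: int = 1000


@dataclass
class BehaviorConfig:
    family_alpha: float = 0.05
    mauchly_alpha: float = 0.05
    mean_now: float = 3.0
    mean_positive: float = 2.3
    mean_negative: float = 2.0
    rating_sd: float = 1.0

    @property
    def condition_means(self) -> dict[str, float]:
        return {"now": self.mean_now, "positive": self.mean_positive,
                "negative": self.mean_negative}


@dataclass
class EffectConfig:
    """Planted signal amplitudes for the synthetic generator (not study facts)."""

    univariate_amplitude: float = 1.0   # % signal change units
    pattern_amplitude: float = 1.0
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 0.5
    connectivity_delta_r: float = 0.4
    beta_jitter_sd: float = 0.5


@dataclass
class PipelineConfig:
    n_subjects: int = 31
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_runs: int = 5
    trials_per_run: int = 36
    n_volumes: int = 380
    seed: int = 0
    glm: GlmConfig = field(default_factory=GlmConfig)
    mvpa: MvpaConfig = field(default_factory=MvpaConfig)
    nbs: NbsConfig = field(default_factory=NbsConfig)
    group: GroupConfig = field(default_factory=GroupConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.validate()

    def validate(self) -> None:
        for name in ("n_subjects", "n_runs", "trials_per_run", "n_volumes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if len(self.grid_shape) != 3 or any(v < 1 for v in self.grid_shape):
            raise ConfigError("grid_shape must be three positive voxel counts")
        if self.tr_s <= 0:
            raise ConfigError("tr_s must be positive")
        if self.voxel_size_mm <= 0:
            raise ConfigError("voxel_size_mm must be positive")
        if self.trials_per_run % 3 != 0:
            raise ConfigError("trials_per_run must be divisible by 3 conditions")

    @property
    def run_length_s(self) -> float:
        return self.n_volumes * self.tr_s

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        d["grid_shape"] = list(self.grid_shape)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        blocks = {"glm": GlmConfig, "mvpa": MvpaConfig, "nbs": NbsConfig,
                  "group": GroupConfig, "behavior": BehaviorConfig,
                  "effects": EffectConfig}
        kwargs: dict = {}
        for key, val in d.items():
            if key in blocks:
                if not isinstance(val, dict):
                    raise ConfigError(f"stage block '{key}' must be a mapping")
                known = {f.name for f in dataclasses.fields(blocks[key])}
                bad = set(val) - known
                if bad:
                    raise ConfigError(f"unknown keys in '{key}' block: {sorted(bad)}")
                kwargs[key] = blocks[key](**val)
            else:
                known = {f.name for f in dataclasses.fields(cls)}
                if key not in known:
                    raise ConfigError(f"unknown config key: {key}")
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)
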