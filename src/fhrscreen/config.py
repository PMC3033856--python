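"""Pipeline configuration: one YAML file with per-stage sections.

All stage parameters and the top-level seed live here; every output
artifact embeds the effective configuration so a run can be reproduced
from its artifacts alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from . import classifier as _clf
from . import emd as _emd
from . import preprocess as _pp
from .errors import ConfigError


@dataclass
class EmdConfig:
    threshold: float = _emd.DEFAULT_SD_THRESHOLD
    max_imfs: int | None = None
    max_iter: int = _emd.DEFAULT_MAX_ITER


@dataclass
class PreprocessConfig:
    alpha: float = _pp.DEFAULT_ALPHA
    jump_bpm: float = _pp.DEFAULT_JUMP_BPM
    bpm_min: float = 50.0
    bpm_max: float = 220.0
    usability_cutoff: float = _pp.DEFAULT_USABILITY_CUTOFF
    interpolate_below_s: float = 0.0


@dataclass
class FeaturesConfig:
    pad: float = 0.0


@dataclass
class SvmConfig:
    C: float = _clf.DEFAULT_C
    gamma: float = _clf.DEFAULT_GAMMA
    weighted: bool = True
    grid_search: bool = False


@dataclass
class EvalConfig:
    k_folds: int = 5


@dataclass
class PipelineConfig:
    emd: EmdConfig = field(default_factory=EmdConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    _SECTIONS = {
        "emd": EmdConfig,
        "preprocess": PreprocessConfig,
        "features": FeaturesConfig,
        "svm": SvmConfig,
        "eval": EvalConfig,
    }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            sections = {}
            for name, section_cls in cls._SECTIONS.items():
                sub = d.get(name, {}) or {}
                known = {x.name for x in fields(section_cls)}
                bad = set(sub) - known
                if bad:
                    raise ConfigError(
                        f"unknown keys in section '{name}': {sorted(bad)}")
                sections[name] = section_cls(**sub)
            return cls(seed=int(d.get("seed", 0)), **sections)
        except ConfigError:
            raise
        except Exception as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                d = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(d)

    def process_kwargs(self) -> dict:
        """Keyword arguments for :func:`fhrscreen.features.process_trace`."""
        return {
            "sd_threshold": self.emd.threshold,
            "max_imfs": self.emd.max_imfs,
            "max_iter": self.emd.max_iter,
            "alpha": self.preprocess.alpha,
            "jump_bpm": self.preprocess.jump_bpm,
            "usability_cutoff": self.preprocess.usability_cutoff,
            "pad": self.features.pad,
        }
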