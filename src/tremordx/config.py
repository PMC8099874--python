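"""Pipeline configuration: defaults, validation, hashing, (de)serialization.

A single master seed fans out to per-stage seeds through a documented
counter scheme (see :func:`stage_seed`), so one knob reproduces every
artifact bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .nn import ConvSpec
from .preprocessing import SpectrogramParams
from .stage1 import CnnConfig

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "validate_config",
    "config_hash",
    "stage_seed",
]

_STAGE_OFFSETS = {"simulate": 0, "split": 1, "stage1": 2, "stage2": 3, "explain": 4}


class ConfigError(ValueError):
    """Invalid or contradictory configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    spectrogram: SpectrogramParams = field(default_factory=SpectrogramParams)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    classifier: str = "qda"  # qda | nb
    shrinkage: float = 0.1
    feature_mode: str = "probabilistic"  # probabilistic | binary
    threshold: float = 1.0
    test_fraction: float = 0.25
    n_repeats: int = 30
    first_visit_only: bool = False
    alpha: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in ("qda", "nb"):
            raise ConfigError(f"unknown classifier: {self.classifier!r}")
        if self.feature_mode not in ("probabilistic", "binary"):
            raise ConfigError(f"unknown feature mode: {self.feature_mode!r}")
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ConfigError("shrinkage must be in [0, 1]")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.threshold <= 0:
            raise ConfigError("threshold must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spectrogram"] = asdict(self.spectrogram)
        d["cnn"] = self.cnn.to_dict()
        return d


def stage_seed(master_seed: int, stage: str, repeat: int = 0) -> int:
    """Derive a deterministic per-stage, per-repeat seed from the master seed."""
    if stage not in _STAGE_OFFSETS:
        raise ConfigError(f"unknown stage: {stage!r}")
    ss = np.random.SeedSequence([int(master_seed), _STAGE_OFFSETS[stage], int(repeat)])
    return int(ss.generate_state(1)[0])


def validate_config(raw: dict | None) -> PipelineConfig:
    """Fill defaults and reject unknown keys / invalid ranges.

    Accepts a (possibly nested) plain dict, e.g. parsed from YAML; an empty
    or None input yields the full default configuration.
    """
    raw = dict(raw or {})
    known_top = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    kwargs: dict = {}
    if "spectrogram" in raw:
        sp = dict(raw.pop("spectrogram") or {})
        bad = set(sp) - set(SpectrogramParams.__dataclass_fields__)
        if bad:
            raise ConfigError(f"unknown spectrogram keys: {sorted(bad)}")
        try:
            kwargs["spectrogram"] = SpectrogramParams(**sp)
        except ValueError as exc:
            raise ConfigError(str(exc)) from None
    if "cnn" in raw:
        cn = dict(raw.pop("cnn") or {})
        bad = set(cn) - set(CnnConfig.__dataclass_fields__)
        if bad:
            raise ConfigError(f"unknown cnn keys: {sorted(bad)}")
        if "conv_specs" in cn:
            cn["conv_specs"] = tuple(
                cs if isinstance(cs, ConvSpec) else ConvSpec(**cs)
                for cs in cn["conv_specs"]
            )
        for tup_key in ("dense_widths", "input_shape"):
            if tup_key in cn:
                cn[tup_key] = tuple(cn[tup_key])
        try:
            kwargs["cnn"] = CnnConfig(**cn)
        except ValueError as exc:
            raise ConfigError(str(exc)) from None
    kwargs.update(raw)
    try:
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from None


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash embedded in every output artifact."""
    canonical = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
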