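"""YAML run configuration with schema validation.

A single YAML file describes a whole pipeline run: phantom generation, coil
simulation, trajectory, noise, network and optimisation settings.  Unknown
keys are rejected; every field has the documented default, so an empty file
is a valid configuration.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .losses import LossWeights
from .networks import DiscriminatorConfig, GeneratorConfig
from .physics import NoiseSpec
from .synthetic import PhantomSpec
from .trajectories import TrajectorySpec
from .training import TrainConfig

__all__ = ["RunConfig", "parse_and_validate", "dump_config"]

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=False)


class PhantomSection(_Strict):
    height: int = 64
    width: int = 64
    n_structures: int = 6
    intensity_min: float = 0.2
    intensity_max: float = 0.95
    edge_sharpness: float = 1.0
    texture_amplitude: float = 0.05
    seed: int = 0

    def to_spec(self) -> PhantomSpec:
        return PhantomSpec(
            shape=(self.height, self.width),
            n_structures=self.n_structures,
            intensity_range=(self.intensity_min, self.intensity_max),
            edge_sharpness=self.edge_sharpness,
            texture_amplitude=self.texture_amplitude,
            seed=self.seed,
        )


class TrajectorySection(_Strict):
    kind: Literal["gaussian2d", "gaussian1d", "poisson2d"] = "gaussian2d"
    fraction: float = Field(0.3, gt=0.0, le=1.0)
    sigma_scale: float = 0.25
    min_radius_scale: float = 1.0
    center_fraction: float = Field(0.0, ge=0.0, lt=1.0)
    seed: int = 0

    def to_spec(self, shape: tuple[int, int]) -> TrajectorySpec:
        return TrajectorySpec(
            kind=self.kind, fraction=self.fraction, shape=shape, seed=self.seed,
            sigma_scale=self.sigma_scale, min_radius_scale=self.min_radius_scale,
            center_fraction=self.center_fraction,
        )


class NoiseSection(_Strict):
    nl: float = Field(0.0, ge=0.0, lt=1.0)
    seed: int = 0

    def to_spec(self) -> NoiseSpec:
        return NoiseSpec(nl=self.nl, seed=self.seed)


class CoilSection(_Strict):
    n_coils: int = Field(4, ge=1)
    seed: int = 0


class GeneratorSection(_Strict):
    base_channels: int = 16
    use_global_residual: bool = True
    use_local_residual: bool = True
    fca_n_frequencies: int = 16
    attention: Literal["fca", "se", "none"] = "fca"

    def to_spec(self) -> GeneratorConfig:
        return GeneratorConfig(
            base_channels=self.base_channels,
            use_global_residual=self.use_global_residual,
            use_local_residual=self.use_local_residual,
            fca_n_frequencies=self.fca_n_frequencies,
            attention=self.attention,
        )


class DiscriminatorSection(_Strict):
    base_channels: int = 16

    def to_spec(self) -> DiscriminatorConfig:
        return DiscriminatorConfig(base_channels=self.base_channels)


class LossSection(_Strict):
    alpha: float = 15.0
    beta: float = 0.1
    gamma: float = 10.0
    mu: float = 0.6
    nu: float = 0.4

    def to_spec(self) -> LossWeights:
        return LossWeights(self.alpha, self.beta, self.gamma, self.mu, self.nu)


class TrainSection(_Strict):
    batch_size: int = 12
    lr_initial: float = 1e-3
    lr_min: float = 1e-5
    lr_decay: float = 0.5
    lr_decay_every: int = 5
    adam_beta1: float = 0.5
    patience: int = Field(8, ge=1)
    max_epochs: int = 20
    seed: int = 0


class DataSection(_Strict):
    n_slices: int = 100
    split_ratio: tuple[int, int, int] = (5, 2, 3)
    split_seed: int = 0


class RunConfig(_Strict):
    """Top-level schema-versioned run configuration."""

    schema_version: int = SCHEMA_VERSION
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    trajectory: TrajectorySection = Field(default_factory=TrajectorySection)
    noise: NoiseSection = Field(default_factory=NoiseSection)
    coils: CoilSection = Field(default_factory=CoilSection)
    generator: GeneratorSection = Field(default_factory=GeneratorSection)
    discriminator: DiscriminatorSection = Field(default_factory=DiscriminatorSection)
    loss: LossSection = Field(default_factory=LossSection)
    train: TrainSection = Field(default_factory=TrainSection)
    data: DataSection = Field(default_factory=DataSection)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {self.schema_version}")
        if self.phantom.height % 16 or self.phantom.width % 16:
            raise ValueError("phantom height/width must be divisible by 16")
        return self

    def to_train_config(self) -> TrainConfig:
        t = self.train
        return TrainConfig(
            batch_size=t.batch_size, lr_initial=t.lr_initial, lr_min=t.lr_min,
            lr_decay=t.lr_decay, lr_decay_every=t.lr_decay_every,
            adam_beta1=t.adam_beta1, patience=t.patience, max_epochs=t.max_epochs,
            seed=t.seed, weights=self.loss.to_spec(),
            generator=self.generator.to_spec(),
            discriminator=self.discriminator.to_spec(),
        )


def parse_and_validate(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file; empty file means all defaults."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a YAML mapping")
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig, path: str | Path | None = None) -> str:
    """Serialize a config back to YAML (round-trips through parse)."""
    text = yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
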