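"""YAML run configuration with strict schema validation.

Unknown keys are rejected so typos fail before any work starts.  The schema
mirrors the pipeline stages; every section has defaults, so an empty config
is a valid full run on the bundled synthetic dataset.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .features import FeatureConfig, STFTConfig
from .pipeline import ExperimentConfig
from .preprocess import PreprocessConfig
from .synth_data import ClassRecipe, SynthConfig, default_recipes

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """A configuration schema violation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthSection(_Strict):
    sample_rate_pool: list[int] = [16_000, 22_050, 44_100]
    duration_range: list[float] = [1.0, 6.0]
    snr_db_range: list[float] = [20.0, 20.0]
    recipes: list[dict] | None = None  # ClassRecipe field overrides

    def build(self, seed: int) -> SynthConfig:
        recipes = (
            tuple(ClassRecipe(**r) for r in self.recipes) if self.recipes else default_recipes()
        )
        return SynthConfig(
            recipes=recipes,
            sample_rate_pool=tuple(self.sample_rate_pool),
            duration_range=tuple(self.duration_range),
            snr_db_range=tuple(self.snr_db_range),
            seed=seed,
        )


class PreprocessSection(_Strict):
    target_rate: int = 10_000
    target_len: int = 30_000
    eval_deterministic: bool = True

    def build(self, seed: int) -> PreprocessConfig:
        return PreprocessConfig(
            target_rate=self.target_rate,
            target_len=self.target_len,
            seed=seed,
            eval_deterministic=self.eval_deterministic,
        )


class FeaturesSection(_Strict):
    frame_len: int = 1024
    hop: int = 512
    window: str = "hann"
    n_filters: int = 128
    n_cepstra: int = 32
    db_floor: float = 1e-10

    def build(self) -> FeatureConfig:
        return FeatureConfig(
            stft=STFTConfig(frame_len=self.frame_len, hop=self.hop, window=self.window),
            n_filters=self.n_filters,
            n_cepstra=self.n_cepstra,
            db_floor=self.db_floor,
        )


class AugmentSection(_Strict):
    rule: str = "below_mean"
    threshold: float | None = None
    classes: list[str] | None = None

    @field_validator("rule")
    @classmethod
    def _known_rule(cls, v: str) -> str:
        if v not in ("below_mean", "below_threshold", "explicit"):
            raise ValueError(f"unknown augmentation rule {v!r}")
        return v


class ModelSection(_Strict):
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    branch_epochs: int = 12
    fusion_epochs: int = 100
    dropout: float = 0.25
    backbones: dict[str, str] | None = None


class EvaluateSection(_Strict):
    folds: int = 5
    test_frac: float = 0.20


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "runs/default"
    synth: SynthSection = Field(default_factory=SynthSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    features: FeaturesSection = Field(default_factory=FeaturesSection)
    augment: AugmentSection = Field(default_factory=AugmentSection)
    model: ModelSection = Field(default_factory=ModelSection)
    evaluate: EvaluateSection = Field(default_factory=EvaluateSection)

    def experiment(self) -> ExperimentConfig:
        return ExperimentConfig(
            preprocess=self.preprocess.build(self.seed),
            features=self.features.build(),
            branch_epochs=self.model.branch_epochs,
            fusion_epochs=self.model.fusion_epochs,
            lr=self.model.lr,
            momentum=self.model.momentum,
            batch_size=self.model.batch_size,
            dropout=self.model.dropout,
            folds=self.evaluate.folds,
            test_frac=self.evaluate.test_frac,
            seed=self.seed,
            backbones=self.model.backbones,
        )


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; ``overrides`` are applied on top."""
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")
        data = loaded
    if overrides:
        data.update(overrides)
    try:
        return RunConfig(**data)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
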