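"""Pipeline configuration: dataclasses with YAML round-trip and validation.

Every random stage must carry an explicit seed; a config without a top-level
seed is rejected at validation time.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Tuple

import yaml

from .synthetic_cohort import CohortSpec
from .texture_features import TextureConfig


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass(frozen=True)
class SelectionConfig:
    n_folds: int = 10
    n_repeats: int = 10
    n_lambda: int = 50
    inner_folds: int = 5
    top_k: int = 10
    seed: int = 0


@dataclass(frozen=True)
class ModelConfig:
    p_enter: float = 0.05
    p_remove: float = 0.1
    ci_level: float = 0.95
    auc_ci_method: str = "delong"


@dataclass(frozen=True)
class ReaderSimConfig:
    """Sensitivity/specificity of each simulated reader in each session."""

    r1_session1: Tuple[float, float] = (1.0, 0.396)
    r2_session1: Tuple[float, float] = (0.937, 0.417)
    r1_session2: Tuple[float, float] = (1.0, 0.604)
    r2_session2: Tuple[float, float] = (0.75, 0.896)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int
    cohort: CohortSpec = field(default_factory=CohortSpec)
    texture: TextureConfig = field(default_factory=TextureConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    readers: ReaderSimConfig = field(default_factory=ReaderSimConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["axis_range"] = list(self.cohort.axis_range)
        for k in ("r1_session1", "r2_session1", "r1_session2", "r2_session2"):
            d["readers"][k] = list(getattr(self.readers, k))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        if not isinstance(d, dict):
            raise ConfigError("configuration must be a mapping")
        if "seed" not in d or d["seed"] is None:
            raise ConfigError("configuration must declare an explicit 'seed'")
        seed = int(d["seed"])
        try:
            cohort_d = dict(d.get("cohort", {}))
            cohort_d.setdefault("seed", seed)
            if "axis_range" in cohort_d:
                cohort_d["axis_range"] = tuple(cohort_d["axis_range"])
            cohort = CohortSpec(**cohort_d)
            texture = TextureConfig(**d.get("texture", {}))
            sel_d = dict(d.get("selection", {}))
            sel_d.setdefault("seed", seed)
            selection = SelectionConfig(**sel_d)
            model = ModelConfig(**d.get("model", {}))
            readers_d = {k: tuple(v) for k, v in d.get("readers", {}).items()}
            readers = ReaderSimConfig(**readers_d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc
        return cls(seed=seed, cohort=cohort, texture=texture,
                   selection=selection, model=model, readers=readers)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Override every stage seed coherently."""
        return replace(
            self, seed=seed,
            cohort=replace(self.cohort, seed=seed),
            selection=replace(self.selection, seed=seed),
        )
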