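"""Run configuration: strict TOML schema shared by all CLI subcommands.

Unknown keys are rejected by name so that typos in audit-trail configs
fail loudly instead of silently falling back to defaults.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, ValidationError

from .optimizer import OptimizerConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OptimizerSettings(_Strict):
    iterations_phase1: int = 3
    iterations_phase2: int = 6
    beam_width: int = 4
    reflections_per_prompt: int = 4
    error_subset_size: int = 4
    seed: int = 0
    uniqueness_scope: Literal["pool", "history"] = "history"
    describe_temperature: float = 0.7
    classify_temperature: float = 0.0
    reflect_temperature: float = 0.7
    modify_temperature: float = 0.7

    def to_optimizer_config(self) -> OptimizerConfig:
        return OptimizerConfig(**self.model_dump())


class BackendSettings(_Strict):
    kind: Literal["simulated", "replay", "api"] = "simulated"
    world_path: Optional[str] = None  # simulated: WorldSpec JSON
    transcript_dir: Optional[str] = None  # replay / recording
    endpoint: Optional[str] = None  # api
    model: Optional[str] = None
    api_key_env: str = "RECAP_API_KEY"
    max_retries: int = 3


class WorldSettings(_Strict):
    n_classes: int = 2
    n_informative: int = 6
    n_decoys: int = 54
    class_prob_high: float = 0.9
    class_prob_low: float = 0.1
    noise: float = 0.05
    seed: int = 11
    n_per_class: int = 30


class RunConfig(_Strict):
    optimizer: OptimizerSettings = OptimizerSettings()
    backend: BackendSettings = BackendSettings()
    world: WorldSettings = WorldSettings()
    lexicon_path: Optional[str] = None
    label_aliases: dict[str, str] = {}
    embedder_dim: int = 768
    log_level: str = "INFO"


class ConfigError(ValueError):
    pass


def load_config(path: str | Path | None) -> RunConfig:
    """Load a TOML run config; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    raw = Path(path).read_text(encoding="utf-8")
    try:
        data = tomllib.loads(raw)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"invalid TOML in {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        names = ", ".join(".".join(str(p) for p in err["loc"]) for err in exc.errors())
        raise ConfigError(f"invalid config {path}: problem with field(s): {names}") from exc
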