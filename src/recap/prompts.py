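"""Prompt objects, roles, phases, and lineage bookkeeping.

Every text instruction flowing through the pipeline is a :class:`Prompt`:
the generation prompt q that elicits an image description, the
classification prompt p that elicits a label, and the reflection /
modification templates that drive the error-feedback loop. Prompts carry
their lineage (parent id, iteration, phase) and a globally monotone
``creation_index`` so that tie-breaking and audit trails are deterministic.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path
from typing import Optional


DEFAULT_SEED_GENERATION_TEXT = (
    "Examine this histology image and describe the visual appearance of the "
    "sample in plain language."
)

DEFAULT_CLASSIFICATION_TEXT = (
    "Given the image and the accompanying findings, assign exactly one "
    "category from the allowed list. Reply with the category name only."
)


class PromptRole(str, enum.Enum):
    GENERATION = "generation"
    CLASSIFICATION = "classification"
    REFLECTION_TEMPLATE = "reflection_template"
    MODIFICATION_TEMPLATE = "modification_template"


class Phase(str, enum.Enum):
    SEED = "seed"
    DIVERSIFY = "diversify"
    OPTIMIZE = "optimize"


@dataclasses.dataclass(frozen=True)
class Prompt:
    """An immutable text instruction with identity and lineage."""

    id: str
    text: str
    role: PromptRole
    parent_id: Optional[str] = None
    iteration: int = 0
    phase: Phase = Phase.SEED
    creation_index: int = 0

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"prompt {self.id!r} has empty text")
        if self.iteration < 0:
            raise ValueError("iteration must be >= 0")
        if self.phase is Phase.SEED and self.parent_id is not None:
            raise ValueError("seed prompts must not have a parent_id")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["role"] = self.role.value
        d["phase"] = self.phase.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Prompt":
        return cls(
            id=d["id"],
            text=d["text"],
            role=PromptRole(d["role"]),
            parent_id=d.get("parent_id"),
            iteration=int(d.get("iteration", 0)),
            phase=Phase(d.get("phase", "seed")),
            creation_index=int(d.get("creation_index", 0)),
        )


class PromptFactory:
    """Mints prompts with strictly increasing creation indices."""

    def __init__(self, start: int = 0) -> None:
        self._next = start

    def make(
        self,
        text: str,
        role: PromptRole,
        *,
        parent: Optional[Prompt] = None,
        iteration: int = 0,
        phase: Phase = Phase.SEED,
    ) -> Prompt:
        idx = self._next
        self._next += 1
        return Prompt(
            id=f"q{idx:04d}",
            text=text,
            role=role,
            parent_id=parent.id if parent is not None else None,
            iteration=iteration,
            phase=phase,
            creation_index=idx,
        )


def save_prompt(directory: str | Path, prompt: Prompt) -> Path:
    """Store a prompt as JSON plus a plain-text export for human review."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{prompt.id}.json"
    path.write_text(json.dumps(prompt.to_dict(), indent=2), encoding="utf-8")
    (directory / f"{prompt.id}.txt").write_text(prompt.text, encoding="utf-8")
    return path


def load_prompt(path: str | Path) -> Prompt:
    return Prompt.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))
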