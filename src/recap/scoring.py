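"""Phase scoring: terminology diversity and training accuracy.

Phase 1 of the optimizer scores each candidate generation prompt q_i by a
diversity measure built from two components over a fixed lexicon:

* T(q_i): the number of distinct lexicon terms matched in the prompt, and
* U(q_i): the number of those terms that appear in no other prompt in the
  comparison scope (the current candidate pool, or the full history of
  generated prompts).

Both are max-normalized over the pool, T~ = T / max_j T(q_j) (0 when the
maximum is 0), likewise U~, and the diversity score is D = T~ + U~ in
[0, 2]. Phase 2 scores prompts by training accuracy
1 - |J_error| / |D|, where J_error is the set of misclassified training
items under that prompt's descriptions.
"""

from __future__ import annotations

import dataclasses
import re
from fractions import Fraction
from functools import lru_cache
from typing import TYPE_CHECKING, Literal, Mapping, Optional, Sequence

from .lexicon import Lexicon, normalize_term
from .prompts import Prompt

if TYPE_CHECKING:  # pragma: no cover
    from .backend import MLLMBackend
    from .corpus import Dataset
    from .optimizer import DescriptionCache

UNPARSED = "<unparsed>"

UniquenessScope = Literal["pool", "history"]


@lru_cache(maxsize=64)
def _compiled_terms(terms: tuple[str, ...]) -> tuple[tuple[str, re.Pattern[str]], ...]:
    # longest (most words, then most characters) first so multi-word terms
    # claim their spans before any sub-term can
    ordered = sorted(terms, key=lambda t: (-len(t.split()), -len(t), t))
    out = []
    for t in ordered:
        pattern = re.compile(r"\b" + r"\s+".join(re.escape(w) for w in t.split()) + r"\b")
        out.append((t, pattern))
    return tuple(out)


def term_set(text: str, lexicon: Lexicon) -> frozenset[str]:
    """Distinct lexicon terms matched in *text*.

    Matching is case-insensitive, ASCII-folded, and word-boundary based;
    multi-word terms are matched before their sub-terms, and a claimed span
    cannot be re-used by a shorter overlapping term.
    """
    norm = normalize_term(text)
    if not norm:
        return frozenset()
    claimed: list[tuple[int, int]] = []
    found: set[str] = set()
    for term, pattern in _compiled_terms(lexicon.terms):
        for m in pattern.finditer(norm):
            span = m.span()
            if any(span[0] < e and s < span[1] for s, e in claimed):
                continue
            claimed.append(span)
            found.add(term)
    return frozenset(found)


def term_count(text: str, lexicon: Lexicon) -> int:
    """T: number of distinct lexicon terms matched in *text* (type-level)."""
    if not len(lexicon):
        raise ValueError("lexicon must be non-empty for diversity scoring")
    return len(term_set(text, lexicon))


def unique_term_count(prompt: Prompt, other_prompts: Sequence[Prompt], lexicon: Lexicon) -> int:
    """U: terms of *prompt* appearing in none of *other_prompts*."""
    if any(o.id == prompt.id for o in other_prompts):
        raise ValueError("prompt must not be a member of other_prompts")
    mine = term_set(prompt.text, lexicon)
    others: set[str] = set()
    for o in other_prompts:
        others |= term_set(o.text, lexicon)
    return len(mine - others)


@dataclasses.dataclass(frozen=True)
class DiversityScore:
    T: int
    U: int
    T_norm: float
    U_norm: float

    def __post_init__(self) -> None:
        if self.U > self.T:
            raise ValueError("U cannot exceed T")

    @property
    def D(self) -> float:
        return self.T_norm + self.U_norm


def pool_diversity(
    pool: Sequence[Prompt],
    lexicon: Lexicon,
    uniqueness_scope: UniquenessScope = "history",
    history: Sequence[Prompt] = (),
) -> dict[str, DiversityScore]:
    """Per-prompt diversity scores over a candidate pool.

    ``uniqueness_scope="pool"`` compares each prompt against the other pool
    members only; ``"history"`` additionally compares against every prompt
    in *history* (prompts sharing the candidate's id are excluded).
    Normalization maxima are always taken over the pool being scored.
    """
    if not pool:
        raise ValueError("pool must be non-empty")
    sets = {q.id: term_set(q.text, lexicon) for q in pool}
    hist_sets = {q.id: term_set(q.text, lexicon) for q in history}
    T = {q.id: len(sets[q.id]) for q in pool}
    U: dict[str, int] = {}
    for q in pool:
        others: set[str] = set()
        for other in pool:
            if other.id != q.id:
                others |= sets[other.id]
        if uniqueness_scope == "history":
            for hid, hset in hist_sets.items():
                if hid != q.id:
                    others |= hset
        U[q.id] = len(sets[q.id] - others)
    maxT = max(T.values())
    maxU = max(U.values())
    return {
        q.id: DiversityScore(
            T=T[q.id],
            U=U[q.id],
            T_norm=T[q.id] / maxT if maxT else 0.0,
            U_norm=U[q.id] / maxU if maxU else 0.0,
        )
        for q in pool
    }


@dataclasses.dataclass(frozen=True)
class ErrorEntry:
    image_id: str
    true_label: str
    predicted_label: str  # UNPARSED sentinel for unparseable replies
    description: str


@dataclasses.dataclass(frozen=True)
class ErrorSet:
    """J_error: the training items misclassified under one generation prompt."""

    entries: tuple[ErrorEntry, ...]
    generation_prompt_id: str

    def __len__(self) -> int:
        return len(self.entries)


def collect_errors(
    dataset: "Dataset",
    classification_prompt: Prompt,
    generation_prompt: Prompt,
    cache: "DescriptionCache",
    backend: "MLLMBackend",
    temperature: float = 0.0,
    aliases: Optional[Mapping[str, str]] = None,
) -> ErrorSet:
    """Classify every item from its cached description and keep the misses.

    Requires the description cache to already hold an entry for every
    (generation prompt, image) pair; unparseable replies are recorded as
    errors with the ``UNPARSED`` sentinel prediction.
    """
    from .inference import parse_label

    entries: list[ErrorEntry] = []
    for item in dataset.items:
        description = cache.get(generation_prompt.id, item.id)
        raw = backend.classify(item, classification_prompt, description, temperature=temperature)
        label, ok = parse_label(raw, dataset.labels, aliases=aliases)
        if not ok:
            entries.append(ErrorEntry(item.id, item.label, UNPARSED, description))
        elif label != item.label:
            entries.append(ErrorEntry(item.id, item.label, label, description))
    return ErrorSet(entries=tuple(entries), generation_prompt_id=generation_prompt.id)


def training_accuracy_exact(error_set: ErrorSet, dataset: "Dataset") -> Fraction:
    """Accuracy as an exact rational: 1 - |J_error| / |D|."""
    n = len(dataset.items)
    if n == 0:
        raise ValueError("dataset is empty")
    return Fraction(n - len(error_set.entries), n)


def training_accuracy(error_set: ErrorSet, dataset: "Dataset") -> float:
    return float(training_accuracy_exact(error_set, dataset))
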