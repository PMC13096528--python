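"""Two-phase, error-driven prompt search with beam retention.

The search maintains a pool of candidate generation prompts. Each
iteration, every pool member's cached descriptions are classified to
collect its error set J_error; l random error subsets per member drive
reflect/modify calls that propose revised prompts; descriptions are
generated once per new prompt (write-once cache); all candidates — the
previous pool plus the revisions — are scored and the top b survive
(threshold at the b-th highest score, ties broken toward the earliest
creation index).

Phase 1 (diversify) scores candidates by terminology diversity D and asks
the modification step for novel terminology; Phase 2 (optimize) scores by
training accuracy. The returned best prompt q* is the argmax of the
Phase-2 score over the final pool regardless of which phase ran last,
since accuracy is the deployment metric.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .backend import (
    BackendError,
    DEFAULT_MODIFICATION_TEMPLATE_TEXT,
    DEFAULT_REFLECTION_TEMPLATE_TEXT,
    DIVERSIFY_MODIFICATION_TEMPLATE_TEXT,
    MLLMBackend,
)
from .corpus import Dataset
from .lexicon import Lexicon
from .prompts import Phase, Prompt, PromptFactory, PromptRole
from .scoring import (
    ErrorSet,
    UniquenessScope,
    collect_errors,
    pool_diversity,
    term_count,
    term_set,
    training_accuracy,
)


class CacheMissError(KeyError):
    pass


class CacheWriteError(ValueError):
    pass


class DescriptionCache:
    """Write-once store of descriptions keyed by (prompt id, image id)."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, str], str] = {}

    def __len__(self) -> int:
        return len(self._store)

    def contains(self, prompt_id: str, image_id: str) -> bool:
        return (prompt_id, image_id) in self._store

    def put(self, prompt_id: str, image_id: str, description: str) -> None:
        key = (prompt_id, image_id)
        if key in self._store:
            raise CacheWriteError(f"description already cached for prompt {prompt_id}, image {image_id}")
        self._store[key] = description

    def get(self, prompt_id: str, image_id: str) -> str:
        try:
            return self._store[(prompt_id, image_id)]
        except KeyError:
            raise CacheMissError(f"no cached description for prompt {prompt_id}, image {image_id}") from None

    def covers(self, prompt: Prompt, dataset: Dataset) -> bool:
        return all(self.contains(prompt.id, item.id) for item in dataset.items)

    def items(self):
        return self._store.items()


@dataclasses.dataclass(frozen=True)
class OptimizerConfig:
    """Search hyperparameters; all fields are recorded in the trace header."""

    iterations_phase1: int = 3
    iterations_phase2: int = 6
    beam_width: int = 4
    reflections_per_prompt: int = 4
    error_subset_size: int = 4
    seed: int = 0
    uniqueness_scope: UniquenessScope = "history"
    describe_temperature: float = 0.7
    classify_temperature: float = 0.0
    reflect_temperature: float = 0.7
    modify_temperature: float = 0.7

    def __post_init__(self) -> None:
        if self.iterations_phase1 < 0 or self.iterations_phase2 < 0:
            raise ValueError("iteration counts must be >= 0")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.reflections_per_prompt < 1:
            raise ValueError("reflections_per_prompt must be >= 1")
        if self.error_subset_size < 1:
            raise ValueError("error_subset_size must be >= 1")
        if self.uniqueness_scope not in ("pool", "history"):
            raise ValueError("uniqueness_scope must be 'pool' or 'history'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class Templates:
    reflection: Prompt
    modification: Prompt
    diversify_modification: Prompt


def default_templates() -> Templates:
    return Templates(
        reflection=Prompt(id="tmpl-reflect", text=DEFAULT_REFLECTION_TEMPLATE_TEXT, role=PromptRole.REFLECTION_TEMPLATE),
        modification=Prompt(id="tmpl-modify", text=DEFAULT_MODIFICATION_TEMPLATE_TEXT, role=PromptRole.MODIFICATION_TEMPLATE),
        diversify_modification=Prompt(
            id="tmpl-modify-diversify",
            text=DIVERSIFY_MODIFICATION_TEMPLATE_TEXT,
            role=PromptRole.MODIFICATION_TEMPLATE,
        ),
    )


@dataclasses.dataclass(frozen=True)
class CandidatePool:
    prompts: tuple[Prompt, ...]
    scores: dict[str, float]
    iteration: int
    phase: Phase

    def __post_init__(self) -> None:
        missing = [q.id for q in self.prompts if q.id not in self.scores]
        if missing:
            raise ValueError(f"pool members without scores: {missing}")


def populate_descriptions(
    prompt: Prompt,
    dataset: Dataset,
    backend: MLLMBackend,
    cache: DescriptionCache,
    temperature: float = 0.7,
) -> DescriptionCache:
    """Generate (once) a description per image under *prompt*.

    Pre-existing cache keys are left untouched, so re-invocation makes no
    backend calls: exactly |D| describe calls per distinct prompt per run.
    """
    if prompt.role is not PromptRole.GENERATION:
        raise ValueError("populate_descriptions requires a generation prompt")
    for item in dataset.items:
        if not cache.contains(prompt.id, item.id):
            try:
                text = backend.describe(item, prompt, temperature=temperature)
            except BackendError as exc:
                raise BackendError(f"describe failed for prompt {prompt.id}, image {item.id}: {exc}") from exc
            cache.put(prompt.id, item.id, text)
    return cache


def sample_error_subsets(
    error_set: ErrorSet,
    l: int,
    subset_size: int,
    rng: np.random.Generator,
) -> list[list]:
    """l error subsets, each drawn without replacement from J_error.

    Subset size is clamped to |J_error|; an empty error set yields no
    subsets (a perfect prompt is carried forward unchanged).
    """
    n = len(error_set.entries)
    if n == 0:
        return []
    size = min(subset_size, n)
    subsets = []
    for _ in range(l):
        picks = rng.choice(n, size=size, replace=False)
        subsets.append([error_set.entries[int(i)] for i in sorted(picks)])
    return subsets


def propose_revisions(
    generation_prompt: Prompt,
    classification_prompt: Prompt,
    subsets: Sequence[Sequence],
    backend: MLLMBackend,
    templates: Templates,
    factory: PromptFactory,
    phase: Phase = Phase.OPTIMIZE,
    iteration: int = 0,
    reflect_temperature: float = 0.7,
    modify_temperature: float = 0.7,
) -> tuple[list[Prompt], list[str], list[str]]:
    """One reflection and one revised prompt per error subset.

    Returns (new prompts H, reflections G, ids of no-op revisions whose
    text equals the parent's). Per-subset backend failures are skipped, so
    H may be shorter than the subset list.
    """
    mod_template = templates.diversify_modification if phase is Phase.DIVERSIFY else templates.modification
    revisions: list[Prompt] = []
    reflections: list[str] = []
    noops: list[str] = []
    for subset in subsets:
        try:
            reflection = backend.reflect(
                classification_prompt, subset, templates.reflection, temperature=reflect_temperature
            )
            text = backend.modify(
                classification_prompt,
                reflection,
                subset,
                mod_template,
                generation_prompt,
                temperature=modify_temperature,
            )
        except BackendError:
            continue
        child = factory.make(text, PromptRole.GENERATION, parent=generation_prompt, iteration=iteration, phase=phase)
        if text == generation_prompt.text:
            noops.append(child.id)
        revisions.append(child)
        reflections.append(reflection)
    return revisions, reflections, noops


def retain_top(prompts: Sequence[Prompt], scores: dict[str, float], b: int) -> list[Prompt]:
    """Keep prompts scoring at or above the b-th highest score.

    When ties at the threshold would exceed b survivors, the pool is
    truncated to exactly b, preferring earlier creation indices. The
    result is ordered by creation index.
    """
    if not prompts:
        raise ValueError("cannot retain from an empty pool")
    ranked = sorted(prompts, key=lambda q: (-scores[q.id], q.creation_index))
    kept = ranked[: min(b, len(ranked))]
    return sorted(kept, key=lambda q: q.creation_index)


@dataclasses.dataclass
class OptimizerResult:
    best: Prompt
    best_score: float
    pool: CandidatePool
    trace: list[dict]
    all_prompts: list[Prompt]
    cache: DescriptionCache
    accuracy_scores: dict[str, float]


class PromptOptimizer:
    """Stateful driver for the two-phase search (Phase 1 diversify, Phase 2 accuracy)."""

    def __init__(
        self,
        dataset: Dataset,
        classification_prompt: Prompt,
        backend: MLLMBackend,
        lexicon: Lexicon,
        config: OptimizerConfig,
        templates: Optional[Templates] = None,
        aliases=None,
    ) -> None:
        if classification_prompt.role is not PromptRole.CLASSIFICATION:
            raise ValueError("classification prompt must have role 'classification'")
        self.dataset = dataset
        self.p = classification_prompt
        self.backend = backend
        self.lexicon = lexicon
        self.config = config
        self.templates = templates or default_templates()
        self.aliases = aliases
        self.cache = DescriptionCache()
        self.history: list[Prompt] = []
        self.trace: list[dict] = []
        self._error_sets: dict[str, ErrorSet] = {}
        self._accuracy: dict[str, float] = {}
        self._by_text: dict[str, Prompt] = {}  # candidate pools are sets: one prompt per text
        self._subset_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
        self._iteration = 0

    # -- cached per-prompt quantities (deterministic backend => stable) ---
    def errors_for(self, prompt: Prompt) -> ErrorSet:
        if prompt.id not in self._error_sets:
            self._error_sets[prompt.id] = collect_errors(
                self.dataset,
                self.p,
                prompt,
                self.cache,
                self.backend,
                temperature=self.config.classify_temperature,
                aliases=self.aliases,
            )
        return self._error_sets[prompt.id]

    def accuracy_for(self, prompt: Prompt) -> float:
        if prompt.id not in self._accuracy:
            self._accuracy[prompt.id] = training_accuracy(self.errors_for(prompt), self.dataset)
        return self._accuracy[prompt.id]

    # -- one loop body ----------------------------------------------------
    def run_iteration(self, pool: CandidatePool, phase: Phase, factory: PromptFactory) -> CandidatePool:
        cfg = self.config
        self._iteration += 1
        candidates: list[Prompt] = list(pool.prompts)
        candidate_ids = {q.id for q in candidates}
        new_ids: list[str] = []
        noop_ids: list[str] = []
        reentered_ids: list[str] = []
        duplicates_skipped = 0
        for q in pool.prompts:
            error_set = self.errors_for(q)
            if not error_set.entries:
                continue  # perfect prompt: nothing to reflect on
            subsets = sample_error_subsets(
                error_set, cfg.reflections_per_prompt, cfg.error_subset_size, self._subset_rng
            )
            revisions, _, noops = propose_revisions(
                q,
                self.p,
                subsets,
                self.backend,
                self.templates,
                factory,
                phase=phase,
                iteration=self._iteration,
                reflect_temperature=cfg.reflect_temperature,
                modify_temperature=cfg.modify_temperature,
            )
            noop_ids.extend(noops)
            for child in revisions:
                # prompt pools are sets of instructions: a revision whose text
                # was already generated is that same element, not a new one
                existing = self._by_text.get(child.text)
                if existing is not None:
                    if existing.id not in candidate_ids:
                        candidates.append(existing)
                        candidate_ids.add(existing.id)
                        reentered_ids.append(existing.id)
                    else:
                        duplicates_skipped += 1
                    continue
                self._by_text[child.text] = child
                populate_descriptions(
                    child, self.dataset, self.backend, self.cache, temperature=cfg.describe_temperature
                )
                candidates.append(child)
                candidate_ids.add(child.id)
                self.history.append(child)
                new_ids.append(child.id)
        if phase is Phase.DIVERSIFY:
            diversity = pool_diversity(
                candidates, self.lexicon, uniqueness_scope=cfg.uniqueness_scope, history=self.history
            )
            scores = {pid: ds.D for pid, ds in diversity.items()}
        else:
            scores = {q.id: self.accuracy_for(q) for q in candidates}
        retained = retain_top(candidates, scores, cfg.beam_width)
        # raw terminology richness/novelty of the survivors (the dynamics
        # quantities; the normalized D above is only the selection score)
        retained_T = [term_count(q.text, self.lexicon) for q in retained]
        hist_sets = {q.id: term_set(q.text, self.lexicon) for q in self.history}
        retained_U = []
        for q in retained:
            others: set[str] = set()
            for hid, hset in hist_sets.items():
                if hid != q.id:
                    others |= hset
            retained_U.append(len(hist_sets[q.id] - others))
        record = {
            "record": "iteration",
            "iteration": self._iteration,
            "phase": phase.value,
            "candidates": [q.id for q in candidates],
            "new_prompts": new_ids,
            "reentered_prompts": reentered_ids,
            "duplicate_revisions_skipped": duplicates_skipped,
            "noop_revisions": noop_ids,
            "pool": [q.id for q in retained],
            "scores": {q.id: scores[q.id] for q in retained},
            "errors": {q.id: len(self.errors_for(q).entries) for q in retained},
            "mean_retained_score": float(np.mean([scores[q.id] for q in retained])),
            "mean_retained_accuracy": float(np.mean([self.accuracy_for(q) for q in retained])),
            "mean_retained_term_count": float(np.mean(retained_T)),
            "mean_retained_unique_count": float(np.mean(retained_U)),
            "uniqueness_scope": cfg.uniqueness_scope,
        }
        self.trace.append(record)
        return CandidatePool(prompts=tuple(retained), scores={q.id: scores[q.id] for q in retained}, iteration=self._iteration, phase=phase)

    # -- full schedule -----------------------------------------------------
    def optimize(self, q0: Prompt) -> OptimizerResult:
        if q0.role is not PromptRole.GENERATION:
            raise ValueError("seed prompt must have role 'generation'")
        cfg = self.config
        factory = PromptFactory(start=q0.creation_index + 1)
        self.history.append(q0)
        self._by_text[q0.text] = q0
        populate_descriptions(q0, self.dataset, self.backend, self.cache, temperature=cfg.describe_temperature)
        self.trace.append(
            {
                "record": "header",
                "config": cfg.to_dict(),
                "seed_prompt": q0.to_dict(),
                "classification_prompt_id": self.p.id,
                "dataset": {"name": self.dataset.name, "size": len(self.dataset.items), "labels": list(self.dataset.labels)},
                "lexicon": {"name": self.lexicon.name, "size": len(self.lexicon)},
            }
        )
        pool = CandidatePool(prompts=(q0,), scores={q0.id: 0.0}, iteration=0, phase=Phase.SEED)
        for _ in range(cfg.iterations_phase1):
            pool = self.run_iteration(pool, Phase.DIVERSIFY, factory)
        for _ in range(cfg.iterations_phase2):
            pool = self.run_iteration(pool, Phase.OPTIMIZE, factory)
        # q* is always selected by the Phase-2 (accuracy) score
        final = sorted(pool.prompts, key=lambda q: (-self.accuracy_for(q), q.creation_index))
        best = final[0]
        best_score = self.accuracy_for(best)
        self.trace.append(
            {
                "record": "result",
                "best_prompt_id": best.id,
                "best_score": best_score,
                "final_pool": [q.id for q in pool.prompts],
                "final_accuracies": {q.id: self.accuracy_for(q) for q in pool.prompts},
            }
        )
        return OptimizerResult(
            best=best,
            best_score=best_score,
            pool=pool,
            trace=self.trace,
            all_prompts=list(self.history),
            cache=self.cache,
            accuracy_scores=dict(self._accuracy),
        )


def optimize(
    dataset: Dataset,
    classification_prompt: Prompt,
    q0: Prompt,
    config: OptimizerConfig,
    backend: MLLMBackend,
    lexicon: Lexicon,
    templates: Optional[Templates] = None,
    aliases=None,
) -> OptimizerResult:
    """Run the full two-phase search and return (q*, trace) bundled in a result."""
    driver = PromptOptimizer(dataset, classification_prompt, backend, lexicon, config, templates, aliases)
    return driver.optimize(q0)
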