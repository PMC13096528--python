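"""Shared fixtures: the default synthetic world and a bank of full-default
optimization runs reused by the slower end-to-end property tests."""

from __future__ import annotations

import pytest

from recap.lexicon import Lexicon
from recap.optimizer import OptimizerConfig, optimize
from recap.prompts import (
    DEFAULT_CLASSIFICATION_TEXT,
    DEFAULT_SEED_GENERATION_TEXT,
    Prompt,
    PromptRole,
)
from recap.world import SimulatedBackend, make_world, sample_dataset

RECOVERY_SEEDS = (1, 2, 3, 4, 5)


def make_seed_prompt() -> Prompt:
    return Prompt(id="q0000", text=DEFAULT_SEED_GENERATION_TEXT, role=PromptRole.GENERATION)


def make_classification_prompt() -> Prompt:
    return Prompt(id="p-classify", text=DEFAULT_CLASSIFICATION_TEXT, role=PromptRole.CLASSIFICATION)


@pytest.fixture(scope="session")
def world():
    return make_world()


@pytest.fixture(scope="session")
def world_lexicon(world):
    return Lexicon.from_terms(world.vocabulary, name="world-vocabulary")


@pytest.fixture()
def classification_prompt():
    return make_classification_prompt()


@pytest.fixture()
def seed_prompt():
    return make_seed_prompt()


@pytest.fixture(scope="session")
def recovery_runs(world, world_lexicon):
    """Five full-default optimization runs on the default world (30/class,
    b=4, l=4, 3 diversify + 6 accuracy iterations), one per seed."""
    runs = []
    for seed in RECOVERY_SEEDS:
        dataset = sample_dataset(world, n_per_class=30, seed=seed)
        backend = SimulatedBackend(world)
        result = optimize(
            dataset,
            make_classification_prompt(),
            make_seed_prompt(),
            OptimizerConfig(seed=seed),
            backend,
            world_lexicon,
        )
        runs.append(
            {
                "seed": seed,
                "dataset": dataset,
                "backend": backend,
                "result": result,
                "coverage": backend.coverage(result.best.text),
            }
        )
    return runs
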