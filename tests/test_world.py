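"""Synthetic world construction and the simulated backend's channel
semantics: deterministic reports, maximum-a-posteriori reading, calibrated
accuracy, and error-driven reflect/modify behavior."""

import numpy as np
import pytest

from recap.lexicon import Lexicon
from recap.optimizer import DescriptionCache, populate_descriptions
from recap.prompts import Prompt, PromptRole
from recap.scoring import collect_errors, training_accuracy
from recap.world import (
    SimulatedBackend,
    WorldSpec,
    analytic_accuracy,
    attach_latents,
    make_world,
    parse_reports,
    render_thumbnail,
    sample_dataset,
    save_latents,
)
from tests.conftest import make_classification_prompt


def full_coverage_prompt(world, pid="qfull"):
    return Prompt(
        id=pid,
        text="Report on: " + "; ".join(world.informative_terms) + ".",
        role=PromptRole.GENERATION,
    )


class TestMakeWorld:
    def test_default_construction(self, world):
        assert len(world.vocabulary) == 60
        assert len(world.informative_terms) == 6
        assert set(world.informative_terms) <= set(world.vocabulary)
        assert world.labels == ("Normal", "Invasive Carcinoma")
        # each class owns a distinct hallmark subset at the high probability
        for vec in world.class_feature_probs:
            assert sorted(set(vec)) == [0.1, 0.9]

    def test_same_seed_reproduces_world(self):
        assert make_world(seed=7) == make_world(seed=7)
        assert make_world(seed=7) != make_world(seed=8)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            make_world(n_informative=0)
        with pytest.raises(ValueError):
            make_world(noise=0.5)
        with pytest.raises(ValueError):
            make_world(class_prob_high=0.1, class_prob_low=0.9)

    def test_json_round_trip(self, world, tmp_path):
        path = world.to_json(tmp_path / "w.json")
        assert WorldSpec.from_json(path) == world


class TestSampleDataset:
    def test_balanced_classes(self, world):
        ds = sample_dataset(world, n_per_class=30, seed=0)
        assert len(ds) == 60
        for label in world.labels:
            assert sum(1 for it in ds.items if it.label == label) == 30

    def test_feature_frequency_matches_bernoulli(self, world):
        # empirical frequency of a p=0.9 hallmark within 3 SE over n=2000
        ds = sample_dataset(world, n_per_class=2000, seed=3)
        label = world.labels[0]
        idx = next(i for i, p in enumerate(world.probs_for(label)) if p == 0.9)
        bits = [it.features[idx] for it in ds.items if it.label == label]
        se = np.sqrt(0.9 * 0.1 / len(bits))
        assert abs(np.mean(bits) - 0.9) < 3 * se

    def test_different_seeds_differ(self, world):
        a = sample_dataset(world, 10, seed=1)
        b = sample_dataset(world, 10, seed=2)
        assert [it.features for it in a.items] != [it.features for it in b.items]
        assert [it.label for it in a.items] == [it.label for it in b.items]

    def test_latents_round_trip(self, world, tmp_path):
        ds = sample_dataset(world, 5, seed=0)
        save_latents(ds, tmp_path / "lat.csv")
        stripped = type(ds)(
            items=tuple(type(it)(id=it.id, label=it.label) for it in ds.items),
            labels=ds.labels,
        )
        back = attach_latents(stripped, tmp_path / "lat.csv")
        assert [it.features for it in back.items] == [it.features for it in ds.items]


class TestDescribe:
    def test_reports_exactly_covered_terms(self, world):
        be = SimulatedBackend(world)
        ds = sample_dataset(world, 2, seed=0)
        two = world.informative_terms[:2]
        q = Prompt(id="q2", text=f"Check {two[0]} and also {two[1]}.", role=PromptRole.GENERATION)
        text = be.describe(ds.items[0], q)
        lines = text.splitlines()
        assert len(lines) == 2
        assert [ln.split(":")[0] for ln in lines] == list(two)
        assert all(ln.split(": ")[1] in ("present", "absent") for ln in lines)

    def test_decoy_terms_ignored(self, world):
        be = SimulatedBackend(world)
        ds = sample_dataset(world, 1, seed=0)
        decoy = next(t for t in world.vocabulary if t not in world.informative_terms)
        q = Prompt(id="qd", text=f"Check {decoy}.", role=PromptRole.GENERATION)
        assert parse_reports(be.describe(ds.items[0], q), world) == {}

    def test_determinism(self, world):
        ds = sample_dataset(world, 2, seed=0)
        q = full_coverage_prompt(world)
        a = SimulatedBackend(world).describe(ds.items[0], q)
        b = SimulatedBackend(world).describe(ds.items[0], q)
        assert a == b

    def test_noiseless_reports_equal_latent_bits(self):
        w0 = make_world(noise=0.0)
        ds = sample_dataset(w0, 3, seed=1)
        be = SimulatedBackend(w0)
        item = ds.items[0]
        reports = parse_reports(be.describe(item, full_coverage_prompt(w0)), w0)
        assert [reports[t] for t in w0.informative_terms] == list(item.features)


class TestClassify:
    def test_noiseless_full_coverage_recovers_truth(self):
        w0 = make_world(noise=0.0)
        ds = sample_dataset(w0, 20, seed=2)
        be = SimulatedBackend(w0)
        q = full_coverage_prompt(w0)
        p = make_classification_prompt()
        wrong = 0
        for item in ds.items:
            desc = be.describe(item, q)
            reply = be.classify(item, p, desc)
            if item.label not in reply:
                wrong += 1
        # distinct MAP class for almost every draw; symmetric ties are rare
        assert wrong <= 1

    def test_zero_coverage_is_chance_level(self, world):
        ds = sample_dataset(world, 200, seed=5)  # n=400
        be = SimulatedBackend(world)
        p = make_classification_prompt()
        correct = sum(
            1 for item in ds.items if item.label in be.classify(item, p, "")
        )
        n = len(ds.items)
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(correct / n - 0.5) < 3 * se

    def test_monotone_coverage_accuracy(self, world):
        # MAP accuracy is non-decreasing in the evidence the prompt requests
        ds = sample_dataset(world, 200, seed=5)
        p = make_classification_prompt()
        accs = []
        for k in (0, 3, 6):
            be = SimulatedBackend(world)
            terms = world.informative_terms[:k]
            q = Prompt(id=f"q{k}", text="Report on: " + "; ".join(terms) if terms else "Describe.", role=PromptRole.GENERATION)
            correct = 0
            for item in ds.items:
                desc = be.describe(item, q)
                correct += item.label in be.classify(item, p, desc)
            accs.append(correct / len(ds.items))
        assert accs[0] <= accs[1] <= accs[2]


class TestCalibration:
    def test_bayes_consistency_noiseless(self):
        # empirical full-coverage accuracy matches the closed-form Bayes
        # accuracy of the Bernoulli mixture within binomial error at n=1000
        w0 = make_world(noise=0.0)
        ds = sample_dataset(w0, 500, seed=9)
        be = SimulatedBackend(w0)
        q = full_coverage_prompt(w0)
        p = make_classification_prompt()
        correct = 0
        for item in ds.items:
            correct += item.label in be.classify(item, p, be.describe(item, q))
        expected = analytic_accuracy(w0)
        n = len(ds.items)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(correct / n - expected) < 3 * se

    def test_analytic_accuracy_limits(self, world):
        assert analytic_accuracy(world, []) == 0.5
        assert 0.9 < analytic_accuracy(world) <= 1.0
        # noise strictly degrades the full-coverage channel
        assert analytic_accuracy(world) < analytic_accuracy(make_world(noise=0.0))


class TestReflectModify:
    def _errors_for(self, world, backend, dataset, q):
        cache = DescriptionCache()
        populate_descriptions(q, dataset, backend, cache)
        return collect_errors(dataset, make_classification_prompt(), q, cache, backend)

    def test_reflection_names_a_missing_informative_term(self, world):
        ds = sample_dataset(world, 30, seed=4)
        be = SimulatedBackend(world)
        q = Prompt(id="q0", text="Describe the tissue.", role=PromptRole.GENERATION)
        errors = self._errors_for(world, be, ds, q)
        assert errors.entries  # zero coverage misclassifies ~half
        from recap.optimizer import default_templates

        reflection = be.reflect(make_classification_prompt(), errors.entries[:4], default_templates().reflection)
        assert any(t in reflection for t in world.informative_terms)

    def test_modify_appends_suggested_terms_and_lineage_is_callers(self, world):
        ds = sample_dataset(world, 30, seed=4)
        be = SimulatedBackend(world)
        q = Prompt(id="q0", text="Describe the tissue.", role=PromptRole.GENERATION)
        errors = self._errors_for(world, be, ds, q)
        from recap.optimizer import default_templates

        tpl = default_templates()
        reflection = be.reflect(make_classification_prompt(), errors.entries[:4], tpl.reflection)
        revised = be.modify(make_classification_prompt(), reflection, errors.entries[:4], tpl.modification, q)
        assert revised.startswith(q.text)
        new_cov = be.coverage(revised)
        assert len(new_cov) > 0

    def test_full_coverage_prompt_yields_noop_revision(self):
        w0 = make_world(noise=0.0)
        ds = sample_dataset(w0, 10, seed=1)
        be = SimulatedBackend(w0)
        q = full_coverage_prompt(w0)
        for item in ds.items:
            be.describe(item, q)
        from recap.optimizer import default_templates

        tpl = default_templates()
        entry_desc = be.describe(ds.items[0], q)
        from recap.scoring import ErrorEntry

        fake = [ErrorEntry(ds.items[0].id, ds.items[0].label, "X", entry_desc)]
        reflection = be.reflect(make_classification_prompt(), fake, tpl.reflection)
        revised = be.modify(make_classification_prompt(), reflection, fake, tpl.modification, q)
        assert revised == q.text

    def test_diversify_template_introduces_novel_vocabulary(self, world):
        ds = sample_dataset(world, 30, seed=4)
        be = SimulatedBackend(world)
        q = Prompt(id="q0", text="Describe the tissue.", role=PromptRole.GENERATION)
        errors = self._errors_for(world, be, ds, q)
        from recap.optimizer import default_templates
        from recap.scoring import term_set

        tpl = default_templates()
        reflection = be.reflect(make_classification_prompt(), errors.entries[:4], tpl.reflection)
        plain = be.modify(make_classification_prompt(), reflection, errors.entries[:4], tpl.modification, q)
        novel = be.modify(
            make_classification_prompt(), reflection, errors.entries[:4], tpl.diversify_modification, q
        )
        vocab_lex = Lexicon.from_terms(world.vocabulary)
        assert len(term_set(novel, vocab_lex)) > len(term_set(plain, vocab_lex)) or plain == novel


class TestThumbnails:
    def test_rendering_is_deterministic_and_feature_dependent(self, world):
        ds = sample_dataset(world, 2, seed=0)
        a = render_thumbnail(ds.items[0], world)
        b = render_thumbnail(ds.items[0], world)
        assert list(a.getdata()) == list(b.getdata())
        different = next(
            it for it in ds.items[1:] if it.features != ds.items[0].features
        )
        c = render_thumbnail(different, world)
        assert list(a.getdata()) != list(c.getdata())
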