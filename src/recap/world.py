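"""Synthetic labeled worlds and the deterministic simulated model backend.

The synthetic world emulates the causal premise of describe-then-classify
diagnosis: each class is characterized by latent binary morphological
features (hallmarks such as nuclear pleomorphism or stromal invasion), and
a description is diagnostic exactly insofar as it reports those features.

A :class:`WorldSpec` fixes a vocabulary V of candidate terms, an
informative subset I whose per-class Bernoulli probabilities carry the
class signal, and a description flip-noise rate. The simulated backend is
a pure function of (world, request, per-request seeded noise):

* describe: for each vocabulary term in the prompt that lies in I, report
  ``term: present`` or ``term: absent`` according to the image's latent
  bit, each report flipped independently with the world's noise rate;
  terms outside I are ignored.
* classify: read the reported features back out of the description and
  return the maximum-a-posteriori class under the world's true Bernoulli
  parameters (uniform prior); with no reported features, draw a label
  uniformly at random (seeded).
* reflect: name the informative terms most often discriminative among the
  error subset's images yet absent from the current prompt's coverage.
* modify: append the reflected terms to the parent prompt; when the
  modification template asks for novel terminology (diversification
  phase), additionally append fresh random vocabulary terms.

Richer prompts therefore yield more diagnostic descriptions, which is the
property the optimizer is supposed to exploit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .backend import BackendError, MLLMBackend
from .corpus import Dataset, LabeledImage
from .lexicon import Lexicon, default_lexicon
from .prompts import Prompt
from .scoring import ErrorEntry, term_set

DEFAULT_LABELS_2 = ("Normal", "Invasive Carcinoma")
DEFAULT_LABELS_3 = ("Normal", "DCIS", "Invasive Carcinoma")

_NOVEL_TERMS_PER_MODIFY = 8  # fresh random vocabulary terms per diversify-phase revision


def derive_seed(*parts) -> int:
    """Stable sub-seed (< 2**31) from arbitrary hashable parts."""
    h = hashlib.sha256(repr(parts).encode("utf-8")).hexdigest()
    return int(h[:8], 16) % (2**31)


def _rng(*parts) -> np.random.Generator:
    return np.random.default_rng(derive_seed(*parts))


@dataclasses.dataclass(frozen=True)
class WorldSpec:
    """Ground truth of a synthetic world."""

    labels: tuple[str, ...]
    vocabulary: tuple[str, ...]
    informative_terms: tuple[str, ...]
    class_feature_probs: tuple[tuple[float, ...], ...]  # aligned with labels x informative_terms
    description_flip_noise: float
    seed: int

    def __post_init__(self) -> None:
        vocab = set(self.vocabulary)
        if not set(self.informative_terms) <= vocab:
            raise ValueError("informative terms must be a subset of the vocabulary")
        if not self.informative_terms:
            raise ValueError("need at least one informative term")
        if len(self.class_feature_probs) != len(self.labels):
            raise ValueError("one probability vector per class required")
        for vec in self.class_feature_probs:
            if len(vec) != len(self.informative_terms):
                raise ValueError("probability vectors must align with informative terms")
            if any(not (0.0 <= p <= 1.0) for p in vec):
                raise ValueError("feature probabilities must lie in [0, 1]")
        if len({tuple(v) for v in self.class_feature_probs}) != len(self.class_feature_probs):
            raise ValueError("class probability vectors must be pairwise distinct")
        if not (0.0 <= self.description_flip_noise < 0.5):
            raise ValueError("flip noise must lie in [0, 0.5)")

    def probs_for(self, label: str) -> tuple[float, ...]:
        return self.class_feature_probs[self.labels.index(label)]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "WorldSpec":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            labels=tuple(d["labels"]),
            vocabulary=tuple(d["vocabulary"]),
            informative_terms=tuple(d["informative_terms"]),
            class_feature_probs=tuple(tuple(v) for v in d["class_feature_probs"]),
            description_flip_noise=float(d["description_flip_noise"]),
            seed=int(d["seed"]),
        )


def make_world(
    n_classes: int = 2,
    n_informative: int = 6,
    n_decoys: int = 54,
    class_prob_high: float = 0.9,
    class_prob_low: float = 0.1,
    noise: float = 0.05,
    seed: int = 11,
    labels: Optional[Sequence[str]] = None,
    lexicon: Optional[Lexicon] = None,
) -> WorldSpec:
    """Construct a world whose vocabulary is drawn from a pathology lexicon.

    Informative term i is assigned probability ``class_prob_high`` in class
    ``i mod n_classes`` and ``class_prob_low`` elsewhere, so every class
    owns a distinct hallmark subset and the full-coverage Bayes reader is
    nearly perfect (see :func:`analytic_accuracy` for the closed form).
    """
    if n_informative < 1:
        raise ValueError("n_informative must be >= 1")
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if not (0.0 <= noise < 0.5):
        raise ValueError("noise must lie in [0, 0.5)")
    if not class_prob_high > class_prob_low:
        raise ValueError("class_prob_high must exceed class_prob_low")
    if labels is None:
        if n_classes == 2:
            labels = DEFAULT_LABELS_2
        elif n_classes == 3:
            labels = DEFAULT_LABELS_3
        else:
            labels = tuple(f"class_{k + 1}" for k in range(n_classes))
    labels = tuple(labels)
    if len(labels) != n_classes:
        raise ValueError("labels must match n_classes")
    lex = lexicon if lexicon is not None else default_lexicon()
    n_vocab = n_informative + n_decoys
    if n_vocab > len(lex):
        raise ValueError(f"lexicon has only {len(lex)} terms, need {n_vocab}")
    rng = _rng(seed, "world-vocab")
    picked = list(rng.choice(len(lex), size=n_vocab, replace=False))
    vocabulary = tuple(lex.terms[i] for i in picked)
    informative = vocabulary[:n_informative]
    probs = tuple(
        tuple(class_prob_high if (i % n_classes) == c else class_prob_low for i in range(n_informative))
        for c in range(n_classes)
    )
    return WorldSpec(
        labels=labels,
        vocabulary=vocabulary,
        informative_terms=informative,
        class_feature_probs=probs,
        description_flip_noise=noise,
        seed=seed,
    )


def _slug(label: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", label.lower()).strip("_")


def sample_dataset(world: WorldSpec, n_per_class: int = 30, seed: int = 0, name: str = "synthetic") -> Dataset:
    """Balanced dataset with i.i.d. class-conditional Bernoulli latent features."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = _rng(world.seed, "dataset", seed)
    items: list[LabeledImage] = []
    for label in world.labels:
        probs = np.asarray(world.probs_for(label))
        for i in range(n_per_class):
            bits = tuple(int(b) for b in (rng.random(len(probs)) < probs))
            items.append(LabeledImage(id=f"{_slug(label)}_{i:04d}", label=label, features=bits))
    return Dataset(items=tuple(items), labels=world.labels, name=name)


def save_latents(dataset: Dataset, path: str | Path) -> Path:
    """Persist latent feature bits so a manifest round-trip can restore them."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["id,label,features"]
    for it in dataset.items:
        if it.features is None:
            raise ValueError(f"item {it.id} has no latent features")
        lines.append(f"{it.id},{it.label}," + "".join(str(b) for b in it.features))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def attach_latents(dataset: Dataset, path: str | Path) -> Dataset:
    """Return a copy of *dataset* with latent features loaded from a latents CSV."""
    table: dict[str, tuple[int, ...]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines()[1:]:
        if not line.strip():
            continue
        iid, _, bits = line.split(",", 2)
        table[iid] = tuple(int(b) for b in bits.strip())
    items = []
    for it in dataset.items:
        if it.id not in table:
            raise ValueError(f"no latent features for item {it.id}")
        items.append(dataclasses.replace(it, features=table[it.id]))
    return Dataset(items=tuple(items), labels=dataset.labels, name=dataset.name)


def analytic_accuracy(world: WorldSpec, coverage: Optional[Sequence[str]] = None) -> float:
    """Expected accuracy of the simulated reader for a given term coverage.

    Enumerates all observed report vectors over the covered informative
    terms. Reports are latent bits flipped with the world's noise rate, so
    an observed bit is Bernoulli(p(1-e) + (1-p)e); the reader's MAP
    decision uses the true (unfolded) parameters with a first-label
    tie-break, exactly as the simulated backend does. Zero coverage falls
    back to the uniform random draw, with expected accuracy 1/|labels|.
    """
    informative = list(world.informative_terms)
    covered = [t for t in (coverage if coverage is not None else informative) if t in informative]
    k = len(covered)
    n_classes = len(world.labels)
    if k == 0:
        return 1.0 / n_classes
    if k > 16:
        raise ValueError("closed-form enumeration supported up to 16 covered terms")
    idx = [informative.index(t) for t in covered]
    eps = world.description_flip_noise
    true_p = np.array([[world.class_feature_probs[c][i] for i in idx] for c in range(n_classes)])
    obs_p = true_p * (1 - eps) + (1 - true_p) * eps
    total = 0.0
    with np.errstate(divide="ignore"):
        log_p = np.log(true_p)
        log_q = np.log(1 - true_p)
    for bits in itertools.product((0, 1), repeat=k):
        b = np.asarray(bits)
        scores = (b * log_p + (1 - b) * log_q).sum(axis=1)
        winner = int(np.argmax(scores))  # argmax takes the first maximum: first-label tie-break
        p_obs_given_c = (obs_p**b * (1 - obs_p) ** (1 - b)).prod(axis=1)
        total += p_obs_given_c[winner]
    return total / n_classes


_REPORT_LINE = re.compile(r"^\s*(.+?):\s*(present|absent)\s*$")
_NO_FEATURES_TEXT = "No specific diagnostic features were assessed in this image."


def parse_reports(description: str, world: WorldSpec) -> dict[str, int]:
    """Read ``term: present/absent`` lines back out of a description."""
    informative = set(world.informative_terms)
    reports: dict[str, int] = {}
    for line in description.splitlines():
        m = _REPORT_LINE.match(line)
        if m and m.group(1).strip() in informative:
            reports[m.group(1).strip()] = 1 if m.group(2) == "present" else 0
    return reports


class SimulatedBackend(MLLMBackend):
    """Deterministic backend obeying a :class:`WorldSpec`.

    All stochastic behavior (report flips, the zero-evidence fallback, the
    novel-vocabulary draw) is seeded per request digest, so caching,
    replay, and call order cannot change any outcome.
    """

    def __init__(self, world: WorldSpec) -> None:
        super().__init__()
        self.world = world
        self.vocab_lexicon = Lexicon.from_terms(world.vocabulary, name="world-vocabulary")
        self._coverage_cache: dict[str, tuple[str, ...]] = {}
        self._registry: dict[str, tuple[int, ...]] = {}

    # -- helpers ---------------------------------------------------------
    def coverage(self, prompt_text: str) -> tuple[str, ...]:
        """Informative terms the prompt asks about, in world order."""
        if prompt_text not in self._coverage_cache:
            matched = term_set(prompt_text, self.vocab_lexicon)
            self._coverage_cache[prompt_text] = tuple(
                t for t in self.world.informative_terms if t in matched
            )
        return self._coverage_cache[prompt_text]

    def register(self, image: LabeledImage) -> None:
        if image.features is not None:
            self._registry[image.id] = image.features

    def _features(self, image_id: str) -> tuple[int, ...]:
        if image_id not in self._registry:
            raise BackendError(f"simulated backend has no latent features for image {image_id}")
        return self._registry[image_id]

    # -- contract hooks --------------------------------------------------
    def _describe(self, image: LabeledImage, prompt: Prompt, temperature: float) -> str:
        if image.features is None and image.id not in self._registry:
            raise BackendError(f"image {image.id} carries no latent features")
        self.register(image)
        features = self._features(image.id)
        covered = self.coverage(prompt.text)
        if not covered:
            return _NO_FEATURES_TEXT
        informative = list(self.world.informative_terms)
        lines = []
        for term in covered:
            bit = features[informative.index(term)]
            # observation noise is a property of (image, feature), not of the
            # prompt wording: re-asking does not re-roll what is visible
            rng = _rng(self.world.seed, "describe-noise", image.id, term)
            if rng.random() < self.world.description_flip_noise:
                bit = 1 - bit
            lines.append(f"{term}: {'present' if bit else 'absent'}")
        return "\n".join(lines)

    def _classify(self, image: LabeledImage, prompt: Prompt, description: str, temperature: float) -> str:
        self.register(image)
        reports = parse_reports(description, self.world)
        if not reports:
            rng = _rng(self.world.seed, "classify-fallback", image.id, prompt.text, description)
            label = self.world.labels[int(rng.integers(len(self.world.labels)))]
            return f"Diagnosis: {label}"
        informative = list(self.world.informative_terms)
        best_label, best_score = None, -np.inf
        for c, label in enumerate(self.world.labels):
            score = 0.0
            for term, bit in reports.items():
                p = self.world.class_feature_probs[c][informative.index(term)]
                score += np.log(p) if bit else np.log(1 - p)
            if score > best_score:  # strict: first label wins ties
                best_label, best_score = label, score
        return f"Diagnosis: {best_label}"

    def _reflect(self, prompt: Prompt, error_subset: Sequence[ErrorEntry], rendered: str, temperature: float) -> str:
        informative = list(self.world.informative_terms)
        covered: set[str] = set()
        for entry in error_subset:
            covered |= set(parse_reports(entry.description, self.world))
        missing = [t for t in informative if t not in covered]
        if not missing:
            return (
                "The descriptions already cover the key diagnostic features; "
                "errors likely stem from reporting noise rather than omitted criteria."
            )
        # a term is discriminative for an error case when the hallmark is
        # actually present and characteristic of the case's true class
        counts: dict[str, int] = {t: 0 for t in missing}
        for entry in error_subset:
            features = self._features(entry.image_id)
            probs = self.world.probs_for(entry.true_label)
            for t in missing:
                i = informative.index(t)
                if probs[i] >= 0.5 and features[i] == 1:
                    counts[t] += 1
        # suggest every missing term achieving the maximal discriminative
        # frequency on this subset: broad when errors are widespread, sharply
        # targeted when only one or two cases remain misclassified
        top = max(counts.values())
        suggested = [t for t in missing if counts[t] == top]
        return (
            "The misclassified cases were described without examining several "
            "discriminative findings. The revised instructions should also ask about: "
            + "; ".join(suggested)
            + "."
        )

    def _modify(
        self,
        prompt: Prompt,
        reflection: str,
        error_subset: Sequence[ErrorEntry],
        rendered: str,
        parent: Prompt,
        temperature: float,
    ) -> str:
        already = term_set(parent.text, self.vocab_lexicon)
        mentioned = term_set(reflection, self.vocab_lexicon)
        # preserve the reflection's ranking (order of first mention)
        suggested = sorted(
            (t for t in self.world.informative_terms if t in mentioned and t not in already),
            key=reflection.find,
        )
        new_terms = list(suggested)
        if "novel terminology" in rendered:
            # a model instructed to explore novel perspectives dilutes the
            # error-driven fix: it keeps only the strongest suggestion and
            # spends the rest of the revision on fresh vocabulary
            new_terms = new_terms[:1]
            rng = _rng(self.world.seed, "modify-novel", parent.text, reflection)
            candidates = [t for t in self.world.vocabulary if t not in already and t not in new_terms]
            n_pick = min(_NOVEL_TERMS_PER_MODIFY, len(candidates))
            if n_pick:
                picks = rng.choice(len(candidates), size=n_pick, replace=False)
                new_terms.extend(candidates[int(i)] for i in sorted(picks))
        if not new_terms:
            return parent.text  # no-op revision; caller flags it in the trace
        return parent.text + " Additionally report on: " + ", ".join(new_terms) + "."


def render_thumbnail(image: LabeledImage, world: WorldSpec, size: int = 48):
    """Small grayscale patch with one visual motif per active latent feature.

    Purely for exercising file-based I/O paths; not a histology simulation.
    """
    from PIL import Image, ImageDraw

    if image.features is None:
        raise ValueError(f"item {image.id} has no latent features to render")
    img = Image.new("L", (size, size), color=220)
    draw = ImageDraw.Draw(img)
    n = len(image.features)
    band = max(size // max(n, 1), 2)
    for i, bit in enumerate(image.features):
        if bit:
            y = (i * band) % (size - band)
            draw.rectangle([2, y, size - 3, y + band - 2], fill=40 + (i * 13) % 120)
    return img
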