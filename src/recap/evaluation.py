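"""Evaluation: confusion matrices, accuracy confidence intervals, and
description-embedding separability.

The separability analysis quantifies whether descriptions generated under
a prompt carry class signal: descriptions are embedded into a fixed-width
semantic space (a deterministic hashed n-gram embedder stands in for a
remote text-embedding model), optionally projected to 2-D with UMAP for
visualization, and scored by the mean silhouette coefficient over the
full-dimensional embeddings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from typing import Optional, Sequence

import numpy as np

from .inference import PredictionRecord

UNPARSED_COLUMN = "<unparsed>"


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """Rows = true labels, columns = predicted labels (+ unparsed sentinel)."""

    labels: tuple[str, ...]
    columns: tuple[str, ...]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        diag = sum(
            self.counts[i, self.columns.index(lbl)]
            for i, lbl in enumerate(self.labels)
            if lbl in self.columns
        )
        return float(diag) / self.total

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "columns": list(self.columns),
            "counts": self.counts.tolist(),
        }


def confusion(records: Sequence[PredictionRecord], label_set: Sequence[str]) -> ConfusionMatrix:
    """Tally true-vs-predicted counts; unparsed records go to a sentinel column."""
    labels = tuple(label_set)
    any_unparsed = any(not r.parsed_ok for r in records)
    columns = labels + ((UNPARSED_COLUMN,) if any_unparsed else ())
    counts = np.zeros((len(labels), len(columns)), dtype=int)
    for r in records:
        if r.true_label is None or r.true_label not in labels:
            raise ValueError(f"record {r.image_id} has true label {r.true_label!r} outside label set")
        i = labels.index(r.true_label)
        if r.parsed_ok and r.predicted_label in labels:
            j = columns.index(r.predicted_label)
        else:
            j = columns.index(UNPARSED_COLUMN)
        counts[i, j] += 1
    return ConfusionMatrix(labels=labels, columns=columns, counts=counts)


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float, float]:
    """Closed-form Wilson score interval for a binomial proportion."""
    from scipy.stats import norm

    if n <= 0:
        raise ValueError("n must be positive")
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie strictly in (0, 1)")
    z = norm.ppf(1 - (1 - level) / 2)
    phat = k / n
    denom = 1 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    lower = max(0.0, center - half)
    upper = min(1.0, center + half)
    return phat, lower, upper


def accuracy_ci(
    records: Sequence[PredictionRecord], method: str = "wilson", level: float = 0.95
) -> tuple[float, float, float]:
    """(accuracy, lower, upper) for a single run of predictions.

    ``wilson`` (default) is the score interval; ``normal`` is the Wald
    approximation. Unparsed records count as errors. Bounds are clipped to
    [0, 1] and always bracket the point estimate.
    """
    if not records:
        raise ValueError("no records")
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie strictly in (0, 1)")
    n = len(records)
    k = sum(1 for r in records if r.parsed_ok and r.predicted_label == r.true_label)
    if method == "wilson":
        return wilson_interval(k, n, level)
    if method == "normal":
        from scipy.stats import norm

        z = norm.ppf(1 - (1 - level) / 2)
        phat = k / n
        half = z * math.sqrt(phat * (1 - phat) / n)
        return phat, max(0.0, phat - half), min(1.0, phat + half)
    raise ValueError(f"unknown CI method {method!r}")


def multirun_ci(accuracies: Sequence[float], level: float = 0.95) -> tuple[float, float, float]:
    """mean +/- t * sd interval across repeated-run accuracies."""
    from scipy.stats import t as t_dist

    if len(accuracies) < 2:
        raise ValueError("need at least two runs")
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie strictly in (0, 1)")
    arr = np.asarray(accuracies, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    half = float(t_dist.ppf(1 - (1 - level) / 2, df=len(arr) - 1)) * sd / math.sqrt(len(arr))
    return mean, max(0.0, mean - half), min(1.0, mean + half)


@dataclasses.dataclass(frozen=True)
class EmbeddingMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray  # one row per description
    empty_ids: tuple[str, ...] = ()  # descriptions embedded as all-zero rows

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix rows must align with ids")
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding matrix must be finite")


class HashedNgramEmbedder:
    """Deterministic text embedder: signed hashed word uni+bigrams, L2-normalized.

    A reproducible stand-in embedding space for tests and offline runs; the
    default width matches common remote text-embedding models (768).
    """

    def __init__(self, dim: int = 768) -> None:
        if dim < 8:
            raise ValueError("embedding dimension too small")
        self.dim = dim

    def _tokens(self, text: str) -> list[str]:
        words = text.lower().split()
        return words + [f"{a} {b}" for a, b in zip(words, words[1:])]

    def embed_one(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=float)
        for tok in self._tokens(text):
            h = int.from_bytes(hashlib.md5(tok.encode("utf-8")).digest()[:8], "little")
            idx = h % self.dim
            sign = 1.0 if (h >> 32) & 1 else -1.0
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        return np.vstack([self.embed_one(t) for t in texts]) if texts else np.zeros((0, self.dim))


def embed_descriptions(
    descriptions: Sequence[tuple[str, str]],
    embedder: Optional[HashedNgramEmbedder] = None,
) -> EmbeddingMatrix:
    """Embed (id, text) pairs; empty/whitespace texts become flagged zero rows."""
    if not descriptions:
        raise ValueError("no descriptions to embed")
    embedder = embedder or HashedNgramEmbedder()
    ids = tuple(i for i, _ in descriptions)
    matrix = embedder.embed([t for _, t in descriptions])
    empty = tuple(i for i, t in descriptions if not t.strip())
    return EmbeddingMatrix(ids=ids, matrix=matrix, empty_ids=empty)


def project_2d(
    embedding: EmbeddingMatrix,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """Seeded 2-D UMAP projection (Euclidean metric) for visualization export."""
    n = embedding.matrix.shape[0]
    if n < n_neighbors + 1:
        raise ValueError(
            f"projection needs at least n_neighbors+1 = {n_neighbors + 1} rows, got {n}; "
            "reduce n_neighbors"
        )
    import umap

    reducer = umap.UMAP(
        n_components=2,
        metric="euclidean",
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(embedding.matrix))


def separation_score(embedding: EmbeddingMatrix | np.ndarray, labels: Sequence[str]) -> float:
    """Mean silhouette coefficient of the full-dimensional embeddings.

    Computed on the original embedding space, never the 2-D projection, so
    the separability claim does not depend on projection hyperparameters.
    Returns 0.0 when all points coincide (no distance structure, hence no
    separation; the silhouette is undefined there).
    """
    from sklearn.metrics import silhouette_score

    X = embedding.matrix if isinstance(embedding, EmbeddingMatrix) else np.asarray(embedding)
    labels = list(labels)
    if X.shape[0] != len(labels):
        raise ValueError("labels must align with embedding rows")
    unique = sorted(set(labels))
    if len(unique) < 2:
        raise ValueError("separation requires at least two distinct labels")
    for u in unique:
        if labels.count(u) < 2:
            raise ValueError(f"label {u!r} has fewer than two members")
    if np.allclose(X, X[0]):
        return 0.0
    return float(silhouette_score(X, labels, metric="euclidean"))
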