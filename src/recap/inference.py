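"""The deployed describe-then-classify pipeline.

``two_step`` mode first elicits a structured description of the image under
the optimized generation prompt, then classifies from the classification
prompt concatenated with that description. ``zero_shot`` mode classifies
from the classification prompt alone (empty description) and serves as the
unoptimized baseline.
"""

from __future__ import annotations

import csv
import dataclasses
import re
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

from .backend import BackendError, CLASSIFY_TEMPERATURE, DESCRIBE_TEMPERATURE, MLLMBackend
from .corpus import Dataset, LabeledImage
from .prompts import Prompt

Mode = Literal["two_step", "zero_shot"]


def parse_label(
    raw_reply: str,
    label_set: Sequence[str],
    aliases: Optional[Mapping[str, str]] = None,
) -> tuple[Optional[str], bool]:
    """Extract a label from raw model text.

    Case-insensitive word-boundary search for each label name (longest
    first) plus any explicit aliases. Exactly one distinct label found
    yields that label; zero or two-plus distinct labels yield
    ``(None, False)``.
    """
    if not label_set:
        raise ValueError("label_set must be non-empty")
    keys: list[tuple[str, str]] = [(lbl, lbl) for lbl in label_set]
    if aliases:
        keys.extend((alias, target) for alias, target in aliases.items())
    keys.sort(key=lambda kv: -len(kv[0]))
    text = raw_reply.lower()
    claimed: list[tuple[int, int]] = []
    found: set[str] = set()
    for key, target in keys:
        pattern = re.compile(r"\b" + r"\s+".join(re.escape(w) for w in key.lower().split()) + r"\b")
        for m in pattern.finditer(text):
            span = m.span()
            if any(span[0] < e and s < span[1] for s, e in claimed):
                continue
            claimed.append(span)
            found.add(target)
    if len(found) == 1:
        return next(iter(found)), True
    return None, False


@dataclasses.dataclass(frozen=True)
class PredictionRecord:
    image_id: str
    true_label: Optional[str]
    predicted_label: Optional[str]
    parsed_ok: bool
    raw_reply: str
    description: str
    generation_prompt_id: Optional[str]
    classification_prompt_id: str

    def __post_init__(self) -> None:
        if not self.parsed_ok and self.predicted_label is not None:
            raise ValueError("unparsed records cannot carry a predicted label")


def predict_one(
    image: LabeledImage,
    q_star: Optional[Prompt],
    p: Prompt,
    backend: MLLMBackend,
    label_set: Sequence[str],
    mode: Mode = "two_step",
    aliases: Optional[Mapping[str, str]] = None,
    describe_temperature: float = DESCRIBE_TEMPERATURE,
    classify_temperature: float = CLASSIFY_TEMPERATURE,
) -> PredictionRecord:
    if mode not in ("two_step", "zero_shot"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "two_step":
        if q_star is None:
            raise ValueError("two_step mode requires a generation prompt")
        description = backend.describe(image, q_star, temperature=describe_temperature)
    else:
        description = ""
    raw = backend.classify(image, p, description, temperature=classify_temperature)
    label, ok = parse_label(raw, label_set, aliases=aliases)
    return PredictionRecord(
        image_id=image.id,
        true_label=image.label,
        predicted_label=label if ok else None,
        parsed_ok=ok,
        raw_reply=raw,
        description=description,
        generation_prompt_id=q_star.id if (mode == "two_step" and q_star) else None,
        classification_prompt_id=p.id,
    )


def predict_dataset(
    dataset: Dataset,
    q_star: Optional[Prompt],
    p: Prompt,
    backend: MLLMBackend,
    mode: Mode = "two_step",
    aliases: Optional[Mapping[str, str]] = None,
) -> tuple[list[PredictionRecord], int]:
    """One prediction per item in dataset order.

    Per-item backend failures are recorded (unparsed, with the error text in
    ``raw_reply``) and the run continues; the second return value counts
    them so callers can reflect failures in their exit status.
    """
    if not dataset.items:
        raise ValueError("dataset is empty")
    records: list[PredictionRecord] = []
    failures = 0
    for item in dataset.items:
        try:
            records.append(
                predict_one(item, q_star, p, backend, dataset.labels, mode=mode, aliases=aliases)
            )
        except BackendError as exc:
            failures += 1
            records.append(
                PredictionRecord(
                    image_id=item.id,
                    true_label=item.label,
                    predicted_label=None,
                    parsed_ok=False,
                    raw_reply=f"<backend error: {exc}>",
                    description="",
                    generation_prompt_id=q_star.id if (mode == "two_step" and q_star) else None,
                    classification_prompt_id=p.id,
                )
            )
    return records, failures


def records_accuracy(records: Sequence[PredictionRecord]) -> float:
    """Fraction of records with a correct parsed prediction (unparsed = wrong)."""
    if not records:
        raise ValueError("no records")
    correct = sum(1 for r in records if r.parsed_ok and r.predicted_label == r.true_label)
    return correct / len(records)


PREDICTION_COLUMNS = ("image_id", "true_label", "predicted_label", "parsed_ok")


def save_predictions(records: Sequence[PredictionRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PREDICTION_COLUMNS)
        for r in records:
            writer.writerow(
                [r.image_id, r.true_label or "", r.predicted_label or "", str(r.parsed_ok).lower()]
            )
    return path


def load_predictions(path: str | Path) -> list[PredictionRecord]:
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            ok = row["parsed_ok"] == "true"
            records.append(
                PredictionRecord(
                    image_id=row["image_id"],
                    true_label=row["true_label"] or None,
                    predicted_label=(row["predicted_label"] or None) if ok else None,
                    parsed_ok=ok,
                    raw_reply="",
                    description="",
                    generation_prompt_id=None,
                    classification_prompt_id="p",
                )
            )
    return records
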