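"""Dataset and run-artifact I/O.

Datasets are described by a CSV manifest with columns ``id,path,label``
(``split`` optional); image paths are interpreted relative to the
manifest's directory and passed opaquely to model backends. Run traces
are append-only JSONL, one record per line.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence


class ManifestError(ValueError):
    """Raised for structural problems in a dataset manifest."""


class TraceError(ValueError):
    """Raised for malformed trace files; names the offending line."""


@dataclasses.dataclass(frozen=True)
class LabeledImage:
    """One labeled item: an image file on disk or an in-memory latent vector."""

    id: str
    label: str
    image_ref: Optional[str] = None
    split: Optional[str] = None
    features: Optional[tuple[int, ...]] = None


@dataclasses.dataclass(frozen=True)
class Dataset:
    items: tuple[LabeledImage, ...]
    labels: tuple[str, ...]
    name: str = "dataset"

    def __post_init__(self) -> None:
        if not self.items:
            raise ManifestError("dataset must contain at least one item")
        seen: set[str] = set()
        for it in self.items:
            if it.id in seen:
                raise ManifestError(f"duplicate id {it.id!r}")
            seen.add(it.id)
            if it.label not in self.labels:
                raise ManifestError(
                    f"item {it.id!r} has label {it.label!r} outside label set {list(self.labels)}"
                )

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def subset(self, split: str) -> "Dataset":
        items = tuple(it for it in self.items if it.split == split)
        return Dataset(items=items, labels=self.labels, name=f"{self.name}:{split}")


REQUIRED_COLUMNS = ("id", "path", "label")


def load_manifest(path: str | Path, label_set: Optional[Sequence[str]] = None) -> Dataset:
    """Read a CSV manifest into a :class:`Dataset`, preserving file order.

    Labels default to the sorted distinct labels observed; passing
    ``label_set`` declares them explicitly and makes out-of-set labels an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in cols]
        if missing:
            raise ManifestError(f"manifest {path} missing column(s): {missing}")
        rows = list(reader)
    base = path.parent
    items = []
    for row in rows:
        ref = row["path"]
        if ref:
            ref = str((base / ref))
        items.append(
            LabeledImage(
                id=row["id"],
                label=row["label"],
                image_ref=ref or None,
                split=row.get("split") or None,
            )
        )
    labels = tuple(label_set) if label_set is not None else tuple(sorted({r["label"] for r in rows}))
    return Dataset(items=tuple(items), labels=labels, name=path.stem)


def save_manifest(dataset: Dataset, path: str | Path) -> Path:
    """Write a dataset back to CSV; paths are stored relative to the manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    has_split = any(it.split for it in dataset.items)
    fields = ["id", "path", "label"] + (["split"] if has_split else [])
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for it in dataset.items:
            ref = it.image_ref or ""
            if ref:
                try:
                    ref = str(Path(ref).relative_to(path.parent))
                except ValueError:
                    pass
            row = {"id": it.id, "path": ref, "label": it.label}
            if has_split:
                row["split"] = it.split or ""
            writer.writerow(row)
    return path


def save_trace(records: Iterable[dict], path: str | Path, append: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mode = "a" if append else "w"
    with path.open(mode, encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return path


def load_trace(path: str | Path) -> list[dict]:
    path = Path(path)
    records = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                records.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise TraceError(f"{path}: malformed trace record at line {lineno}") from exc
    return records
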