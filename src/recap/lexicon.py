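"""Term lexicons for diversity scoring.

The diversity objective counts "biomedical terms" in a prompt. What counts
as a term is operationalized as membership in an explicit, auditable
lexicon: a plain-text file, one lowercase term per line (multi-word terms
allowed), ``#`` for comments. A default pathology lexicon of ~150
morphology terms ships with the package.
"""

from __future__ import annotations

import dataclasses
import unicodedata
from importlib import resources
from pathlib import Path
from typing import Iterable


def normalize_term(term: str) -> str:
    """Lowercase, ASCII-fold, and collapse internal whitespace."""
    folded = unicodedata.normalize("NFKD", term)
    folded = "".join(ch for ch in folded if not unicodedata.combining(ch))
    return " ".join(folded.lower().split())


@dataclasses.dataclass(frozen=True)
class Lexicon:
    """An ordered, duplicate-free set of normalized terms."""

    terms: tuple[str, ...]
    name: str = "lexicon"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.terms:
            if t != normalize_term(t):
                raise ValueError(f"term {t!r} is not normalized")
            if t in seen:
                raise ValueError(f"duplicate term {t!r} after normalization")
            seen.add(t)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in set(self.terms)

    @classmethod
    def from_terms(cls, terms: Iterable[str], name: str = "lexicon") -> "Lexicon":
        out: list[str] = []
        seen: set[str] = set()
        for t in terms:
            n = normalize_term(t)
            if n and n not in seen:
                out.append(n)
                seen.add(n)
        return cls(terms=tuple(out), name=name)

    @classmethod
    def from_file(cls, path: str | Path) -> "Lexicon":
        path = Path(path)
        lines = path.read_text(encoding="utf-8").splitlines()
        terms = []
        for line in lines:
            line = line.split("#", 1)[0].strip()
            if line:
                terms.append(line)
        return cls.from_terms(terms, name=path.stem)


def default_lexicon() -> Lexicon:
    """The packaged pathology lexicon."""
    ref = resources.files("recap.data") / "pathology_lexicon.txt"
    with resources.as_file(ref) as path:
        lex = Lexicon.from_file(path)
    return dataclasses.replace(lex, name="pathology_default")
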