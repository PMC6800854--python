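"""Corpus and segmentation file I/O.

File formats
------------
Corpus file
    UTF-8 text, one ``word<TAB>count`` per line.
Segmentation file
    One ``word<TAB>morph1 morph2 ...`` per line (space-separated morphs);
    a '+'-joined morph string (``morph1+morph2``) is accepted on read.
Surprisal file
    TSV with columns ``word<TAB>model<TAB>bits``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


@dataclass
class TokenCounts:
    """Word-to-token-frequency table standing for a training corpus."""

    entries: dict[str, int]
    total_tokens: int = 0
    alphabet: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("corpus must contain at least one word")
        if not self.total_tokens:
            self.total_tokens = sum(self.entries.values())
        if not self.alphabet:
            self.alphabet = {c for w in self.entries for c in w}
        for w, c in self.entries.items():
            if c < 1:
                raise ValueError(f"count for {w!r} must be >= 1, got {c}")

    def __len__(self) -> int:
        return len(self.entries)

    def filtered(self, min_count: int) -> "TokenCounts":
        """Drop entries below *min_count* and recompute totals."""
        kept = {w: c for w, c in self.entries.items() if c >= min_count}
        if not kept:
            raise ValueError("no entries remain after frequency filtering")
        return TokenCounts(kept)


def load_corpus(path: str | Path, min_count: int = 1) -> TokenCounts:
    """Read a ``word<TAB>count`` corpus file.

    Raises ``ValueError`` naming the offending line number on malformed
    input, and if no entries survive the *min_count* filter.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    entries: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0]:
                raise ValueError(f"malformed line {lineno}: {line!r}")
            word, count_str = parts
            try:
                count = int(count_str)
            except ValueError:
                raise ValueError(f"malformed line {lineno}: {line!r}") from None
            if count < 0:
                raise ValueError(f"malformed line {lineno}: negative count")
            entries[word] = entries.get(word, 0) + count
    entries = {w: c for w, c in entries.items() if c >= min_count and c > 0}
    if not entries:
        raise ValueError("corpus is empty after filtering")
    return TokenCounts(entries)


def save_corpus(counts: TokenCounts, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for w in sorted(counts.entries):
            fh.write(f"{w}\t{counts.entries[w]}\n")


def load_segmentations(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a ``word<TAB>morphs`` segmentation lexicon."""
    segs: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed line {lineno}: {line!r}")
            word, morph_str = parts
            morphs = tuple(
                m for m in morph_str.replace("+", " ").split(" ") if m
            )
            if "".join(morphs) != word:
                raise ValueError(
                    f"line {lineno}: morphs do not concatenate to {word!r}"
                )
            segs[word] = morphs
    return segs


def save_segmentations(
    segs: Mapping[str, Iterable[str]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for w in sorted(segs):
            fh.write(f"{w}\t{' '.join(segs[w])}\n")


def save_surprisals(
    values: Mapping[str, float], model_name: str, path: str | Path,
    append: bool = False,
) -> None:
    mode = "a" if append else "w"
    with open(path, mode, encoding="utf-8") as fh:
        for w in sorted(values):
            fh.write(f"{w}\t{model_name}\t{values[w]:.6f}\n")


def load_surprisals(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a surprisal TSV into ``{model: {word: bits}}``."""
    out: dict[str, dict[str, float]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed line {lineno}: {line!r}")
            word, model, bits = parts
            out.setdefault(model, {})[word] = float(bits)
    return out
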