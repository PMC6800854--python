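"""Per-word self-information and set-level cross-entropy.

Every trained model (word/morph n-gram, MDL segmentation, category-HMM)
exposes ``self_information(word) -> bits | None`` and a ``name``; this
module provides the shared scoring surface over that protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, runtime_checkable


@runtime_checkable
class SurprisalModel(Protocol):
    name: str

    def self_information(self, word: str) -> float | None: ...


@dataclass
class SurprisalVector:
    """Self-information (bits) per word under one model.

    ``values`` holds only scorable words; ``unscorable`` lists words the
    model explicitly could not score (propagated downstream as missing).
    """

    model_name: str
    values: dict[str, float]
    unscorable: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = {w: v for w, v in self.values.items() if v < 0}
        if bad:
            raise ValueError(f"negative self-information: {bad}")

    def __getitem__(self, word: str) -> float:
        return self.values[word]

    def mean(self) -> float:
        if not self.values:
            raise ValueError("empty surprisal vector")
        return sum(self.values.values()) / len(self.values)


def self_information(model: SurprisalModel, word: str) -> float | None:
    """Self-information of *word* in bits; ``None`` marks unscorable."""
    return model.self_information(word)


def score_words(model: SurprisalModel, words: Iterable[str]) -> SurprisalVector:
    values: dict[str, float] = {}
    unscorable: list[str] = []
    for w in words:
        si = model.self_information(w)
        if si is None:
            unscorable.append(w)
        else:
            values[w] = si
    return SurprisalVector(model.name, values, tuple(unscorable))


def cross_entropy(model: SurprisalModel, words: Iterable[str]) -> float:
    """Mean self-information over *words* (bits/word).

    Shares its code path with :func:`score_words` so it is bit-identical
    to the mean of the corresponding surprisal vector.  Any unscorable
    word is an error, never a silent drop.
    """
    words = list(words)
    if not words:
        raise ValueError("word list must be non-empty")
    vec = score_words(model, words)
    if vec.unscorable:
        raise ValueError(
            f"unscorable words under {model.name}: {list(vec.unscorable)}"
        )
    return vec.mean()
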