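"""Morph segmentations and boundary-level evaluation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

#: Morphotactic category labels used by the category-HMM model.
CATEGORIES = ("prefix", "stem", "suffix", "non-morpheme")


@dataclass(frozen=True)
class Segmentation:
    """An ordered morph analysis of one word.

    The concatenation of ``morphs`` must equal ``word`` exactly; if
    ``categories`` is present it is aligned one-to-one with ``morphs``.
    """

    word: str
    morphs: tuple[str, ...]
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.morphs:
            raise ValueError("morphs list must be non-empty")
        if any(not m for m in self.morphs):
            raise ValueError("morphs must be non-empty strings")
        if "".join(self.morphs) != self.word:
            raise ValueError(
                f"morphs {self.morphs!r} do not concatenate to {self.word!r}"
            )
        if self.categories is not None:
            if len(self.categories) != len(self.morphs):
                raise ValueError("categories must align with morphs")
            bad = set(self.categories) - set(CATEGORIES)
            if bad:
                raise ValueError(f"unknown categories: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.morphs)

    @property
    def boundaries(self) -> frozenset[int]:
        """Internal split positions (offsets into the word, 1..len-1)."""
        pos, out = 0, []
        for m in self.morphs[:-1]:
            pos += len(m)
            out.append(pos)
        return frozenset(out)


def boundary_prf(
    predicted: Sequence[Segmentation], gold: Sequence[Segmentation]
) -> tuple[float, float, float]:
    """Micro-averaged boundary precision, recall and F1.

    Boundaries are internal split positions; the word lists must be paired
    (same words, same order).
    """
    if len(predicted) != len(gold):
        raise ValueError("predicted and gold lists differ in length")
    tp = fp = fn = 0
    for p, g in zip(predicted, gold):
        if p.word != g.word:
            raise ValueError(f"word mismatch: {p.word!r} vs {g.word!r}")
        pb, gb = p.boundaries, g.boundaries
        tp += len(pb & gb)
        fp += len(pb - gb)
        fn += len(gb - pb)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1
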