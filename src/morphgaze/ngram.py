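"""Word-, morph- and letter-level n-gram language models.

The word unigram model is a maximum-likelihood estimate over surface
frequencies; the morph unigram and bigram models are trained on
pre-segmented input (the supervised comparison point to the unsupervised
MDL segmentation models).  All self-information values are in bits
(log base 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpusio import TokenCounts
from .segmentation import Segmentation

WORD_START = "<w>"
WORD_END = "</w>"

LOG2 = math.log(2.0)


# ---------------------------------------------------------------------------
# letter n-gram (pseudoword generation and OOV fallback scoring)
# ---------------------------------------------------------------------------

class LetterNgram:
    """Additively smoothed letter n-gram over word types.

    Used for two jobs: generating pseudowords that follow the letter
    statistics of the real vocabulary, and assigning a fallback probability
    to out-of-vocabulary strings.
    """

    BOS = "^"
    EOS = "$"

    def __init__(self, order: int = 3, smoothing: float = 0.1) -> None:
        if order < 1:
            raise ValueError("order must be >= 1")
        self.order = order
        self.smoothing = smoothing
        self._counts: dict[str, dict[str, float]] = {}
        self.alphabet: list[str] = []

    def fit(self, words: Iterable[str]) -> "LetterNgram":
        letters: set[str] = set()
        counts: dict[str, dict[str, float]] = {}
        k = self.order - 1
        for w in words:
            letters.update(w)
            padded = self.BOS * k + w + self.EOS
            for i in range(k, len(padded)):
                ctx = padded[i - k : i]
                counts.setdefault(ctx, {}).setdefault(padded[i], 0.0)
                counts[ctx][padded[i]] += 1.0
        if not letters:
            raise ValueError("no training words")
        self.alphabet = sorted(letters)
        self._counts = counts
        return self

    def _prob(self, ctx: str, sym: str) -> float:
        row = self._counts.get(ctx, {})
        vocab = len(self.alphabet) + 1  # + end symbol
        total = sum(row.values()) + self.smoothing * vocab
        return (row.get(sym, 0.0) + self.smoothing) / total

    def logprob(self, s: str, include_end: bool = True) -> float:
        """log2 probability of the string (with boundary padding)."""
        k = self.order - 1
        padded = self.BOS * k + s + (self.EOS if include_end else "")
        lp = 0.0
        for i in range(k, len(padded)):
            lp += math.log(self._prob(padded[i - k : i], padded[i])) / LOG2
        return lp

    def sample_word(self, length: int, rng: np.random.Generator) -> str:
        """Sample a string of exactly *length* letters (end symbol barred)."""
        k = self.order - 1
        out = self.BOS * k
        for _ in range(length):
            ctx = out[-k:] if k else ""
            probs = np.array(
                [self._prob(ctx, c) for c in self.alphabet], dtype=float
            )
            probs /= probs.sum()
            out += self.alphabet[int(rng.choice(len(self.alphabet), p=probs))]
        return out[k:] if k else out


# ---------------------------------------------------------------------------
# word / morph n-gram models
# ---------------------------------------------------------------------------

_KNOWN_SMOOTHING = ("ml", "absolute_discount")


@dataclass
class NgramModel:
    """Unigram or bigram model over words or morphs.

    ``probs`` maps a context tuple (empty for unigrams, previous unit for
    bigrams) to a unit->probability table.  For morph-unit models the
    training segmentations are retained so stimulus words can be scored by
    their morph analyses.
    """

    order: int
    unit: str  # "word" | "morph"
    probs: dict[tuple[str, ...], dict[str, float]]
    smoothing: dict
    name: str
    boundary_symbols: tuple[str, str] = (WORD_START, WORD_END)
    segmentations: dict[str, tuple[str, ...]] = field(default_factory=dict)
    letter_model: LetterNgram | None = None
    total_tokens: int = 0
    _backoff: dict[str, float] = field(default_factory=dict)

    # -- scoring -----------------------------------------------------------

    def prob(self, ctx: tuple[str, ...], u: str) -> float | None:
        """Full (interpolated) probability of unit *u* after *ctx*.

        Returns ``None`` when the model assigns no probability mass (e.g.
        an unseen event under unsmoothed maximum likelihood).
        """
        row = self.probs.get(ctx)
        p = row.get(u) if row else None
        if p is not None:
            return p
        if self.order == 2 and self.smoothing.get("method") == "absolute_discount":
            # interpolated absolute discounting: unseen events after a seen
            # context receive discount-mass times the lower-order estimate;
            # a wholly unseen context backs off to the lower order directly
            bo = self._backoff.get(u)
            if bo is None:
                return None
            if row is None:
                return bo
            lam = self.smoothing.get("_lambda", {}).get(ctx, 0.0)
            return lam * bo
        return None

    def _unit_logp(self, ctx: tuple[str, ...], u: str) -> float | None:
        p = self.prob(ctx, u)
        if p is None or p <= 0.0:
            return self._oov_logp(u)
        return math.log(p) / LOG2

    def _oov_logp(self, u: str) -> float | None:
        if self.smoothing.get("oov") == "strict" or self.letter_model is None:
            return None
        # letter-model fallback, scaled below the least frequent real unit
        lp = self.letter_model.logprob(u)
        return lp - math.log(self.total_tokens + 1.0) / LOG2

    def self_information(
        self, word: str, segmentation: Sequence[str] | None = None
    ) -> float | None:
        """Per-word self-information in bits; ``None`` if unscorable."""
        if self.unit == "word":
            lp = self._unit_logp((), word)
            return None if lp is None else -lp
        morphs = (
            tuple(segmentation)
            if segmentation is not None
            else self.segmentations.get(word)
        )
        if morphs is None:
            return None
        total = 0.0
        if self.order == 1:
            for m in morphs:
                lp = self._unit_logp((), m)
                if lp is None:
                    return None
                total += lp
        else:
            prev = self.boundary_symbols[0]
            for m in list(morphs) + [self.boundary_symbols[1]]:
                lp = self._unit_logp((prev,), m)
                if lp is None:
                    return None
                total += lp
                prev = m
        return max(-total, 0.0)


def train_word_unigram(
    corpus: TokenCounts, oov_policy: str = "fallback", name: str = "word_unigram"
) -> NgramModel:
    """Maximum-likelihood word unigram over surface frequencies."""
    if not corpus.entries:
        raise ValueError("empty corpus")
    n = corpus.total_tokens
    probs = {(): {w: c / n for w, c in corpus.entries.items()}}
    letter = LetterNgram(order=3).fit(corpus.entries) if oov_policy == "fallback" else None
    return NgramModel(
        order=1,
        unit="word",
        probs=probs,
        smoothing={"method": "ml", "oov": oov_policy},
        name=name,
        letter_model=letter,
        total_tokens=n,
    )


def train_morph_ngram(
    segmented_corpus: Mapping[str, tuple[Segmentation | Sequence[str], int]],
    order: int,
    smoothing: dict | None = None,
    name: str | None = None,
) -> NgramModel:
    """Train a morph unigram (order 1) or bigram (order 2).

    *segmented_corpus* maps each word to ``(segmentation, token count)``.
    The default smoothing is interpolated absolute discounting with a
    discount of 0.5 (recorded in the descriptor); ``{"method": "ml"}``
    requests unsmoothed maximum likelihood.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    smoothing = dict(smoothing or {"method": "absolute_discount", "discount": 0.5})
    if smoothing.get("method") not in _KNOWN_SMOOTHING:
        raise ValueError(f"unknown smoothing descriptor: {smoothing!r}")

    segs: dict[str, tuple[str, ...]] = {}
    for w, (seg, _c) in segmented_corpus.items():
        morphs = seg.morphs if isinstance(seg, Segmentation) else tuple(seg)
        Segmentation(w, tuple(morphs))  # validates
        segs[w] = tuple(morphs)

    probs: dict[tuple[str, ...], dict[str, float]] = {}
    backoff: dict[str, float] = {}
    total_tokens = 0

    if order == 1:
        counts: dict[str, float] = {}
        for w, (_seg, c) in segmented_corpus.items():
            for m in segs[w]:
                counts[m] = counts.get(m, 0.0) + c
                total_tokens += c
        n = sum(counts.values())
        if smoothing["method"] == "ml":
            probs[()] = {m: c / n for m, c in counts.items()}
        else:
            d = float(smoothing.get("discount", 0.5))
            v = len(counts)
            lam = d * v / n
            probs[()] = {
                m: (c - d) / n + lam / v for m, c in counts.items()
            }
    else:
        big: dict[str, dict[str, float]] = {}
        uni: dict[str, float] = {}
        for w, (_seg, c) in segmented_corpus.items():
            prev = WORD_START
            for m in list(segs[w]) + [WORD_END]:
                big.setdefault(prev, {}).setdefault(m, 0.0)
                big[prev][m] += c
                uni[m] = uni.get(m, 0.0) + c
                total_tokens += c
                prev = m
        n_uni = sum(uni.values())
        backoff = {m: c / n_uni for m, c in uni.items()}
        lambdas: dict[tuple[str, ...], float] = {}
        if smoothing["method"] == "ml":
            for h, row in big.items():
                tot = sum(row.values())
                probs[(h,)] = {m: c / tot for m, c in row.items()}
        else:
            d = float(smoothing.get("discount", 0.5))
            for h, row in big.items():
                tot = sum(row.values())
                n1p = len(row)
                lam = d * n1p / tot
                lambdas[(h,)] = lam
                probs[(h,)] = {
                    m: (max(c - d, 0.0) / tot) + lam * backoff[m]
                    for m, c in row.items()
                }
                # interpolated mass for events unseen after h is handled at
                # scoring time via lambda * backoff
        smoothing["_lambda"] = lambdas

    letter = LetterNgram(order=3).fit(segs)
    return NgramModel(
        order=order,
        unit="morph",
        probs=probs,
        smoothing=smoothing,
        name=name or ("morph_unigram" if order == 1 else "morph_bigram"),
        segmentations=segs,
        letter_model=letter,
        total_tokens=int(total_tokens),
        _backoff=backoff,
    )
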