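"""Unsupervised MDL-based morphological segmentation.

The model stores a lexicon of morphs and a segmentation of every training
word.  Its two-part cost is

``total = lexicon_cost + alpha * corpus_cost``

where the lexicon cost is the code length of every stored morph string
under a fixed letter distribution (including an end-of-morph marker), and
the corpus cost is the token-weighted self-information of the morph
sequence under the maximum-likelihood unigram over current lexicon counts:

``corpus_cost = N * log2(N) - sum_m c_m * log2(c_m)``.

The corpus weight ``alpha`` trades storage against encoding: a small
``alpha`` lets the lexicon term dominate, yielding a compact inventory of
short, morph-like units; a large ``alpha`` makes the corpus term dominate,
which favours whole-word units (one token per occurrence is the cheapest
encoding).

Training is coordinate descent over words: each word's segmentation is
re-optimized given everything else, candidates are evaluated on the exact
incremental cost, and a change is accepted only if it does not increase
the total, so the accepted cost is non-increasing.  For short words the
candidate set is the exhaustive set of segmentations; for longer words
candidates come from a dynamic program over split points that scores each
substring with an additive approximation of its cost contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .corpusio import TokenCounts
from .segmentation import Segmentation

LOG2 = math.log(2.0)
END_MARKER = "#"
_COST_EPS = 1e-9


@dataclass
class MorfessorParams:
    """Training hyperparameters.

    alpha
        Weight on the corpus (data) part of the two-part cost; > 0.
    seed
        Seed for the per-epoch word shuffles and random-restart inits.
    max_epochs / convergence_tol
        Stop when the relative cost decrease over an epoch falls below the
        tolerance, or after ``max_epochs`` epochs (with a warning flag).
    use_type_counts
        Train on type counts (every word weight 1) instead of token counts.
    exact_enum_max_len
        Words up to this length get an exhaustive candidate set
        (``2**(L-1)`` segmentations); longer words use the DP proposal.
    n_restarts
        Number of optimization starts: the first is deterministic
        (whole-word init), the rest are random splits; the lowest-cost
        final state wins.
    """

    alpha: float = 1.0
    seed: int = 0
    max_epochs: int = 12
    convergence_tol: float = 1e-4
    use_type_counts: bool = False
    exact_enum_max_len: int = 6
    n_restarts: int = 1
    random_split_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


def letter_probs_from_corpus(corpus: TokenCounts) -> dict[str, float]:
    """Type-weighted letter distribution plus an end-of-morph marker.

    Every word type contributes its letters once, plus one end marker;
    add-one smoothing keeps all alphabet characters representable.
    """
    counts: dict[str, float] = {c: 1.0 for c in corpus.alphabet}
    counts[END_MARKER] = 1.0
    for w in corpus.entries:
        for c in w:
            counts[c] += 1.0
        counts[END_MARKER] += 1.0
    total = sum(counts.values())
    return {c: k / total for c, k in counts.items()}


def seg_key(morphs: tuple[str, ...]) -> tuple:
    """Deterministic tie-break: fewer morphs, then leftmost-longest."""
    return (len(morphs), tuple(-len(m) for m in morphs))


def _all_segmentations(word: str) -> list[tuple[str, ...]]:
    n = len(word)
    out = []
    for mask in range(1 << (n - 1)):
        morphs, start = [], 0
        for i in range(1, n):
            if mask & (1 << (i - 1)):
                morphs.append(word[start:i])
                start = i
        morphs.append(word[start:])
        out.append(tuple(morphs))
    return out


@dataclass
class MorfessorModel:
    """A trained MDL segmentation model."""

    lexicon: dict[str, int]
    segmentations: dict[str, Segmentation]
    letter_probs: dict[str, float]
    params: MorfessorParams
    final_cost: float
    word_counts: dict[str, int]
    converged: bool = True
    name: str = "morfessor"
    #: accepted total cost after each epoch of the winning start
    cost_trace: list[float] = field(default_factory=list, repr=False)
    _letter_cost_cache: dict[str, float] = field(default_factory=dict, repr=False)

    @property
    def total_morph_tokens(self) -> int:
        return sum(self.lexicon.values())

    def letter_cost(self, morph: str) -> float:
        """Code length of a morph string in bits under ``letter_probs``."""
        cached = self._letter_cost_cache.get(morph)
        if cached is not None:
            return cached
        lp = self.letter_probs
        floor = min(lp.values()) / 10.0
        bits = -math.log(lp.get(END_MARKER, floor)) / LOG2
        for c in morph:
            bits += -math.log(lp.get(c, floor)) / LOG2
        self._letter_cost_cache[morph] = bits
        return bits

    # -- scoring -----------------------------------------------------------

    def self_information(self, word: str) -> float | None:
        """Surprisal in bits: re-Viterbi analysis, summed morph code length."""
        seg, bits = self._viterbi(word, fallback=True)
        if seg is None:
            return None
        return max(bits, 0.0)

    def segment(self, word: str, fallback: bool = True) -> Segmentation | None:
        return viterbi_segment(self, word, fallback=fallback)

    def mean_morphs(self, words: Iterable[str]) -> float:
        lens = []
        for w in words:
            seg = self.segment(w)
            if seg is not None:
                lens.append(len(seg))
        if not lens:
            raise ValueError("no scorable words")
        return float(np.mean(lens))

    def _viterbi(
        self, word: str, fallback: bool
    ) -> tuple[tuple[str, ...] | None, float]:
        """Best-probability split into lexicon morphs.

        DP over split points maximizing the product of ML unigram morph
        probabilities; unknown morphs are scored by the letter model
        (scaled below any stored morph) when *fallback* is on.  Returns
        ``(morphs, total_bits)`` or ``(None, inf)`` when unscorable.
        """
        if not word:
            raise ValueError("word must be non-empty")
        n_tok = self.total_morph_tokens
        if fallback and any(c not in self.letter_probs for c in word):
            # still scorable through the letter-cost floor
            pass
        elif not fallback and any(
            c not in self.letter_probs or c == END_MARKER for c in word
        ):
            return None, math.inf
        L = len(word)
        oov_pen = math.log(n_tok + 1.0) / LOG2

        def morph_bits(m: str) -> float | None:
            c = self.lexicon.get(m, 0)
            if c > 0:
                return -math.log(c / n_tok) / LOG2
            if not fallback:
                return None
            return self.letter_cost(m) + oov_pen

        # best[j]: (bits, n_morphs, neg-length profile, morphs) for word[:j]
        best: list[tuple | None] = [None] * (L + 1)
        best[0] = (0.0, 0, (), ())
        for j in range(1, L + 1):
            for i in range(j):
                if best[i] is None:
                    continue
                bits = morph_bits(word[i:j])
                if bits is None:
                    continue
                b0, k0, prof0, m0 = best[i]
                cand = (
                    b0 + bits,
                    k0 + 1,
                    prof0 + (-(j - i),),
                    m0 + (word[i:j],),
                )
                if best[j] is None or (
                    round(cand[0] - best[j][0], 9),
                    cand[1],
                    cand[2],
                ) < (0.0, best[j][1], best[j][2]):
                    best[j] = cand
        if best[L] is None:
            return None, math.inf
        bits, _k, _prof, morphs = best[L]
        return morphs, bits


def viterbi_segment(
    model: MorfessorModel, word: str, fallback: bool = True
) -> Segmentation | None:
    """Segment *word* into the model's morphs, maximizing unigram probability.

    Returns ``None`` (unscorable) when fallback is off and no path through
    stored morphs exists.
    """
    morphs, _bits = model._viterbi(word, fallback=fallback)
    if morphs is None:
        return None
    return Segmentation(word, morphs)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

_NLOGN_CACHE: dict[int, float] = {}


def _nlogn(n: int) -> float:
    got = _NLOGN_CACHE.get(n)
    if got is None:
        got = _NLOGN_CACHE[n] = n * math.log(n)
    return got


class _CostState:
    """Incrementally maintained two-part cost."""

    __slots__ = ("c", "n", "sum_clog", "lex_cost", "alpha", "_lcost", "lp_floor", "lp")

    def __init__(self, alpha: float, letter_probs: dict[str, float]) -> None:
        self.c: dict[str, int] = {}
        self.n = 0
        self.sum_clog = 0.0
        self.lex_cost = 0.0
        self.alpha = alpha
        self.lp = letter_probs
        self.lp_floor = min(letter_probs.values()) / 10.0
        self._lcost: dict[str, float] = {}

    def letter_cost(self, m: str) -> float:
        got = self._lcost.get(m)
        if got is not None:
            return got
        bits = -math.log(self.lp.get(END_MARKER, self.lp_floor)) / LOG2
        for ch in m:
            bits += -math.log(self.lp.get(ch, self.lp_floor)) / LOG2
        self._lcost[m] = bits
        return bits

    def add(self, m: str, k: int) -> None:
        c0 = self.c.get(m, 0)
        if c0:
            self.sum_clog -= _nlogn(c0)
        else:
            self.lex_cost += self.letter_cost(m)
        c1 = c0 + k
        self.c[m] = c1
        self.sum_clog += _nlogn(c1)
        self.n += k

    def remove(self, m: str, k: int) -> None:
        c0 = self.c[m]
        self.sum_clog -= _nlogn(c0)
        c1 = c0 - k
        if c1 < 0:
            raise AssertionError("negative morph count")
        if c1:
            self.c[m] = c1
            self.sum_clog += _nlogn(c1)
        else:
            del self.c[m]
            self.lex_cost -= self.letter_cost(m)
        self.n -= k

    def total(self) -> float:
        if self.n == 0:
            return self.lex_cost
        corpus = (self.n * math.log(self.n) - self.sum_clog) / LOG2
        return self.lex_cost + self.alpha * corpus


def total_cost(
    segmentations: Mapping[str, tuple[str, ...]],
    word_counts: Mapping[str, int],
    letter_probs: Mapping[str, float],
    alpha: float,
) -> float:
    """Two-part cost of a full joint segmentation, computed from scratch.

    This is the plain (non-incremental) definition; the brute-force
    reference optimizer below is built on it and the trainer is checked
    against that optimizer in the tests.
    """
    counts: dict[str, int] = {}
    for w, morphs in segmentations.items():
        k = word_counts[w]
        for m in morphs:
            counts[m] = counts.get(m, 0) + k
    n = sum(counts.values())
    corpus = sum(c * (math.log(n) - math.log(c)) for c in counts.values()) / LOG2
    floor = min(letter_probs.values()) / 10.0
    end_bits = -math.log(letter_probs.get(END_MARKER, floor)) / LOG2
    lex = 0.0
    for m in counts:
        lex += end_bits
        for ch in m:
            lex += -math.log(letter_probs.get(ch, floor)) / LOG2
    return lex + alpha * corpus


def exhaustive_optimum(
    word_counts: Mapping[str, int],
    alpha: float,
    letter_probs: Mapping[str, float] | None = None,
) -> tuple[dict[str, tuple[str, ...]], float]:
    """Brute-force joint cost minimizer over all segmentations of all words.

    Exponential; intended for toy corpora only (a handful of short words).
    Ties are broken by the per-word tie-break key applied over words in
    sorted order.
    """
    if letter_probs is None:
        letter_probs = letter_probs_from_corpus(TokenCounts(dict(word_counts)))
    words = sorted(word_counts)
    per_word = [_all_segmentations(w) for w in words]
    n_joint = 1
    for opts in per_word:
        n_joint *= len(opts)
        if n_joint > 5_000_000:
            raise ValueError("corpus too large for exhaustive search")

    best_cost = math.inf
    best_key: tuple | None = None
    best: dict[str, tuple[str, ...]] | None = None
    idx = [0] * len(words)
    while True:
        segs = {w: per_word[i][idx[i]] for i, w in enumerate(words)}
        cost = total_cost(segs, word_counts, letter_probs, alpha)
        key = tuple(seg_key(segs[w]) for w in words)
        if (
            cost < best_cost - _COST_EPS
            or (abs(cost - best_cost) <= _COST_EPS and key < best_key)
        ):
            best_cost, best_key, best = cost, key, segs
        # advance odometer
        for i in range(len(words) - 1, -1, -1):
            idx[i] += 1
            if idx[i] < len(per_word[i]):
                break
            idx[i] = 0
        else:
            break
    assert best is not None
    return best, best_cost


def train_morfessor_baseline(
    corpus: TokenCounts,
    params: MorfessorParams | None = None,
    name: str | None = None,
) -> MorfessorModel:
    """Train the MDL segmentation model on a token-count corpus."""
    if not corpus.entries:
        raise ValueError("empty corpus")
    params = params or MorfessorParams()
    letter_probs = letter_probs_from_corpus(corpus)
    counts = (
        {w: 1 for w in corpus.entries}
        if params.use_type_counts
        else dict(corpus.entries)
    )
    words = sorted(counts)
    enum_cap = params.exact_enum_max_len
    alpha = params.alpha

    best_state: tuple | None = None
    for restart in range(params.n_restarts):
        rng = np.random.default_rng((params.seed + restart) % (2**31))
        state = _CostState(alpha, letter_probs)
        segs: dict[str, tuple[str, ...]] = {}
        for w in words:
            if restart == 0 or len(w) == 1:
                morphs = (w,)  # whole-word start (deterministic)
            elif restart == 1:
                morphs = tuple(w)  # fully letterized start
            else:
                morphs = _random_split(w, rng, params.random_split_prob)
            segs[w] = morphs
            for m in morphs:
                state.add(m, counts[w])

        converged = False
        trace = [state.total()]
        prev = trace[0]
        for _epoch in range(params.max_epochs):
            order = list(words)
            rng.shuffle(order)
            for w in order:
                segs[w] = _optimize_word(w, counts[w], segs[w], state, enum_cap)
            _refine_lexicon(segs, state)
            _merge_pass(segs, state, counts)
            now = state.total()
            trace.append(now)
            if prev - now < params.convergence_tol * max(abs(prev), 1.0):
                converged = True
                break
            prev = now

        # canonicalization: deterministic sorted-order passes to a fixed point
        for _ in range(3):
            changed = False
            for w in words:
                new = _optimize_word(w, counts[w], segs[w], state, enum_cap)
                if new != segs[w]:
                    changed = True
                segs[w] = new
            if not changed:
                break

        final = state.total()
        trace.append(final)
        if best_state is None or final < best_state[0] - _COST_EPS:
            best_state = (final, dict(segs), converged, trace)

    final_cost, segs, converged, trace = best_state
    lexicon: dict[str, int] = {}
    for w, morphs in segs.items():
        for m in morphs:
            lexicon[m] = lexicon.get(m, 0) + counts[w]
    model = MorfessorModel(
        lexicon=lexicon,
        segmentations={w: Segmentation(w, m) for w, m in segs.items()},
        letter_probs=letter_probs,
        params=params,
        final_cost=final_cost,
        word_counts=counts,
        converged=converged,
        name=name or f"morfessor_{params.alpha:g}",
        cost_trace=trace,
    )
    return model


def _random_split(
    word: str, rng: np.random.Generator, p: float
) -> tuple[str, ...]:
    morphs, start = [], 0
    for i in range(1, len(word)):
        if rng.random() < p:
            morphs.append(word[start:i])
            start = i
    morphs.append(word[start:])
    return tuple(morphs)


def _optimize_word(
    word: str,
    count: int,
    current: tuple[str, ...],
    state: _CostState,
    enum_cap: int,
) -> tuple[str, ...]:
    """Conditionally re-segment one word; never increases the exact cost."""
    for m in current:
        state.remove(m, count)

    L = len(word)
    if L == 1:
        candidates: list[tuple[str, ...]] = [(word,)]
    elif L <= enum_cap:
        candidates = _all_segmentations(word)
    else:
        candidates = [current, (word,), _dp_proposal(word, count, state)]

    best: tuple[str, ...] | None = None
    best_cost = math.inf
    best_key: tuple | None = None
    cur_cost = None
    for cand in candidates:
        for m in cand:
            state.add(m, count)
        cost = state.total()
        for m in cand:
            state.remove(m, count)
        if cand == current:
            cur_cost = cost
        key = seg_key(cand)
        if cost < best_cost - _COST_EPS or (
            abs(cost - best_cost) <= _COST_EPS and key < best_key
        ):
            best, best_cost, best_key = cand, cost, key

    # keep the current analysis on exact ties unless the tie-break prefers
    # the challenger; `current` is always in the candidate set for long
    # words, and for enumerated words it is one of the candidates anyway
    if cur_cost is not None and best_cost > cur_cost - _COST_EPS:
        if not (abs(best_cost - cur_cost) <= _COST_EPS and best_key < seg_key(current)):
            best = current
    for m in best:
        state.add(m, count)
    return best


def _apply_morph_split(
    segs: dict[str, tuple[str, ...]],
    index: dict[str, set[str]],
    m: str,
    parts: tuple[str, str],
) -> None:
    a, b = parts
    for w in index.pop(m, ()):
        new_seg: list[str] = []
        for piece in segs[w]:
            if piece == m:
                new_seg.extend(parts)
            else:
                new_seg.append(piece)
        segs[w] = tuple(new_seg)
        index.setdefault(a, set()).add(w)
        index.setdefault(b, set()).add(w)


def _refine_lexicon(
    segs: dict[str, tuple[str, ...]], state: _CostState
) -> None:
    """Global splitting moves over shared substructure (exact-cost descent).

    Two move families that per-word optimization cannot express, both
    applying one shared decision to *every* occurrence at once so the
    lexicon cost of a new unit is amortized over the words that use it:

    1. morph resplit — replace a lexicon morph by its best binary split
       everywhere it occurs;
    2. shared-affix split — peel a common suffix (or prefix) off all
       lexicon morphs that carry it, in one joint move.

    (The complementary fusing move lives in :func:`_merge_pass`.)  Moves
    are accepted only when the exact total cost decreases, so the pass
    is a strict descent and terminates.
    """
    index: dict[str, set[str]] = {}
    for w, morphs in segs.items():
        for m in morphs:
            index.setdefault(m, set()).add(w)

    # -- 1. per-morph resplit (queued so new parts are revisited) ----------
    queue = sorted(state.c, key=lambda m: (-state.c[m], m))
    while queue:
        next_queue: list[str] = []
        for m in queue:
            c = state.c.get(m)
            if c is None or len(m) < 2:
                continue
            base = state.total()
            best_delta, best_parts = 0.0, None
            state.remove(m, c)
            for i in range(1, len(m)):
                a, b = m[:i], m[i:]
                state.add(a, c)
                state.add(b, c)
                delta = state.total() - base
                state.remove(a, c)
                state.remove(b, c)
                if delta < best_delta - _COST_EPS:
                    best_delta, best_parts = delta, (a, b)
            if best_parts is None:
                state.add(m, c)
                continue
            state.add(best_parts[0], c)
            state.add(best_parts[1], c)
            _apply_morph_split(segs, index, m, best_parts)
            next_queue.extend(p for p in best_parts if len(p) >= 2)
        queue = sorted(set(next_queue), key=lambda m: (-state.c.get(m, 0), m))

    # -- 2. shared-affix splits -------------------------------------------
    for side in ("suffix", "prefix"):
        groups: dict[str, list[str]] = {}
        for m in state.c:
            if len(m) < 2:
                continue
            for k in range(1, len(m)):
                affix = m[-k:] if side == "suffix" else m[:k]
                groups.setdefault(affix, []).append(m)
        for affix, members in sorted(groups.items()):
            members = [m for m in members if m in state.c]
            if len(members) < 2:
                continue
            remainders = {
                m[: -len(affix)] if side == "suffix" else m[len(affix):]
                for m in members
            }
            if remainders & set(members):
                # a member is another member's remainder; the bulk move
                # would double-book counts, leave it to the other passes
                continue
            base = state.total()
            moves = []
            for m in members:
                c = state.c[m]
                if side == "suffix":
                    parts = (m[: -len(affix)], affix)
                else:
                    parts = (affix, m[len(affix):])
                moves.append((m, c, parts))
                state.remove(m, c)
                state.add(parts[0], c)
                state.add(parts[1], c)
            if state.total() < base - _COST_EPS:
                for m, _c, parts in moves:
                    _apply_morph_split(segs, index, m, parts)
            else:
                for m, c, parts in reversed(moves):
                    state.remove(parts[1], c)
                    state.remove(parts[0], c)
                    state.add(m, c)

def _merge_pass(
    segs: dict[str, tuple[str, ...]],
    state: _CostState,
    counts: Mapping[str, int],
) -> None:
    """Fuse adjacent morph pairs everywhere they occur when that lowers
    the exact cost; repeat until no merge is accepted."""
    changed = True
    while changed:
        changed = False
        pair_tokens: dict[tuple[str, str], int] = {}
        pair_words: dict[tuple[str, str], list[str]] = {}
        for w, morphs in segs.items():
            for a, b in zip(morphs, morphs[1:]):
                pair_tokens[(a, b)] = pair_tokens.get((a, b), 0) + counts[w]
                pair_words.setdefault((a, b), []).append(w)
        for (a, b), k in sorted(
            pair_tokens.items(), key=lambda kv: (-kv[1], kv[0])
        ):
            # stale pairs can linger after an accepted merge
            k_now = 0
            ws = []
            for w in set(pair_words[(a, b)]):
                n_here = sum(
                    1 for x, y in zip(segs[w], segs[w][1:])
                    if (x, y) == (a, b)
                )
                if n_here:
                    k_now += n_here * counts[w]
                    ws.append(w)
            if not k_now:
                continue
            base = state.total()
            state.remove(a, k_now)
            state.remove(b, k_now)
            state.add(a + b, k_now)
            if state.total() < base - _COST_EPS:
                merged = a + b
                for w in ws:
                    out: list[str] = []
                    i = 0
                    ms = segs[w]
                    while i < len(ms):
                        if i + 1 < len(ms) and ms[i] == a and ms[i + 1] == b:
                            out.append(merged)
                            i += 2
                        else:
                            out.append(ms[i])
                            i += 1
                    segs[w] = tuple(out)
                changed = True
            else:
                state.remove(a + b, k_now)
                state.add(a, k_now)
                state.add(b, k_now)


def _dp_proposal(
    word: str, count: int, state: _CostState
) -> tuple[str, ...]:
    """Best segmentation under an additive approximation of the cost.

    Each candidate morph is charged its marginal corpus bits at the counts
    it would have after insertion, plus its lexicon string cost if new.
    Interactions between morphs in the same word are ignored; the caller
    re-evaluates the proposal on the exact cost.  Ties fall to the split
    with the longer final morph (the exact re-evaluation applies the full
    tie-break afterwards).
    """
    L = len(word)
    alpha_over_log2 = state.alpha / LOG2
    n0 = state.n
    cget = state.c.get
    log = math.log
    log_denom = log(n0 + count)
    lcost = state.letter_cost

    best = [0.0] * (L + 1)
    back = [0] * (L + 1)
    for j in range(1, L + 1):
        bj = math.inf
        bi = 0
        for i in range(j):
            m = word[i:j]
            c0 = cget(m, 0)
            u = (
                best[i]
                + (0.0 if c0 else lcost(m))
                + count * (log_denom - log(c0 + count)) * alpha_over_log2
            )
            if u < bj - 1e-12:
                bj = u
                bi = i
        best[j] = bj
        back[j] = bi
    morphs: list[str] = []
    j = L
    while j > 0:
        i = back[j]
        morphs.append(word[i:j])
        j = i
    morphs.reverse()
    return tuple(morphs)
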