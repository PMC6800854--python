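"""Flat category-HMM over MDL segmentations.

A light-weight structured counterpart to the plain MDL segmentation
model: morphs carry morphotactic categories (prefix, stem, suffix,
non-morpheme) and the word is scored as the best path through a hidden
Markov model over those categories.  Word-start and word-end act as
pseudo-categories; morphotactically impossible transitions (word-start to
suffix, prefix to word-end) have probability zero throughout.

The model is initialized from distributional heuristics on the base
segmentations (affix-like morphs have high context diversity on one side
and avoid edge positions on the other) and refined with Viterbi-EM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .corpusio import TokenCounts
from .morfessor import MorfessorModel, LOG2
from .segmentation import CATEGORIES, Segmentation

START = "<start>"
END = "<end>"
PREFIX, STEM, SUFFIX, NON = CATEGORIES

#: transitions with probability pinned to zero
FORBIDDEN: frozenset[tuple[str, str]] = frozenset(
    {(START, SUFFIX), (PREFIX, END)}
)

_STATES = list(CATEGORIES)


@dataclass
class CategoryModel:
    """Category-HMM fitted on top of a trained MDL segmentation model."""

    transitions: dict[tuple[str, str], float]
    emissions: dict[str, dict[str, float]]
    base_segmenter: MorfessorModel
    name: str = "catmap"
    _em_floor: dict[str, float] = field(default_factory=dict)

    # -- scoring -----------------------------------------------------------

    def _emit_logp(self, cat: str, morph: str) -> float | None:
        p = self.emissions.get(cat, {}).get(morph)
        if p is None or p <= 0.0:
            # unseen morph: letter-model fallback through the base lexicon
            base = self.base_segmenter
            floor = self._em_floor.get(cat)
            if floor is None:
                return None
            return -base.letter_cost(morph) * LOG2 + math.log(floor)
        return math.log(p)

    def viterbi_path(
        self, morphs: tuple[str, ...]
    ) -> tuple[tuple[str, ...], float] | None:
        """Best category path and its log2 probability (incl. start/end)."""
        trans = self.transitions
        prev_scores: dict[str, tuple[float, tuple[str, ...]]] = {}
        for s in _STATES:
            t = trans.get((START, s), 0.0)
            e = self._emit_logp(s, morphs[0])
            if t > 0.0 and e is not None:
                prev_scores[s] = (math.log(t) + e, (s,))
        for m in morphs[1:]:
            cur: dict[str, tuple[float, tuple[str, ...]]] = {}
            for s in _STATES:
                e = self._emit_logp(s, m)
                if e is None:
                    continue
                best = None
                for s0, (sc, path) in prev_scores.items():
                    t = trans.get((s0, s), 0.0)
                    if t <= 0.0:
                        continue
                    cand = (sc + math.log(t) + e, path + (s,))
                    if best is None or cand[0] > best[0]:
                        best = cand
                if best is not None:
                    cur[s] = best
            prev_scores = cur
            if not prev_scores:
                return None
        best = None
        for s0, (sc, path) in prev_scores.items():
            t = trans.get((s0, END), 0.0)
            if t <= 0.0:
                continue
            cand = (sc + math.log(t), path)
            if best is None or cand[0] > best[0]:
                best = cand
        if best is None:
            return None
        return best[1], best[0] / LOG2

    def self_information(self, word: str) -> float | None:
        seg = self.base_segmenter.segment(word)
        if seg is None:
            return None
        got = self.viterbi_path(seg.morphs)
        if got is None:
            return None
        _path, log2p = got
        return max(-log2p, 0.0)

    def categorize(self, word: str) -> Segmentation | None:
        seg = self.base_segmenter.segment(word)
        if seg is None:
            return None
        got = self.viterbi_path(seg.morphs)
        if got is None:
            return None
        return Segmentation(seg.word, seg.morphs, got[0])


def _initial_categories(base: MorfessorModel) -> dict[str, list[str]]:
    """Heuristic per-occurrence category priors for every morph.

    Scores follow positional and contextual diversity statistics over the
    base segmentations: morphs concentrated in final position with many
    distinct left neighbours lean suffix, initial-position morphs with
    diverse right contexts lean prefix or stem, long morphs lean stem,
    and very short high-frequency strings are allowed as non-morphemes.
    """
    left: dict[str, set[str]] = {}
    right: dict[str, set[str]] = {}
    pos_counts: dict[str, dict[str, float]] = {}
    for w, seg in base.segmentations.items():
        cnt = base.word_counts.get(w, 1)
        ms = seg.morphs
        for i, m in enumerate(ms):
            left.setdefault(m, set()).add(ms[i - 1] if i > 0 else START)
            right.setdefault(m, set()).add(ms[i + 1] if i < len(ms) - 1 else END)
            slot = (
                "solo"
                if len(ms) == 1
                else "first" if i == 0 else "last" if i == len(ms) - 1 else "mid"
            )
            pos_counts.setdefault(m, {}).setdefault(slot, 0.0)
            pos_counts[m][slot] += cnt

    paths: dict[str, list[str]] = {}
    for m in left:
        pos = pos_counts[m]
        tot = sum(pos.values())
        non_initial = (pos.get("last", 0) + pos.get("mid", 0)) / tot
        non_final = (pos.get("first", 0) + pos.get("mid", 0)) / tot
        suffix_score = len(left[m]) * non_initial / max(len(m), 1)
        prefix_score = len(right[m]) * non_final / max(len(m), 1)
        stem_score = len(m) * (pos.get("solo", 0) + pos.get("first", 0) + 1) / tot
        scores = {SUFFIX: suffix_score, PREFIX: prefix_score, STEM: stem_score}
        if len(m) <= 2 and tot > 1:
            scores[NON] = 0.3 * suffix_score
        order = sorted(scores, key=lambda s: -scores[s])
        paths[m] = order
    return paths


def train_catmap(
    corpus: TokenCounts,
    base: MorfessorModel,
    n_em_iters: int = 5,
    name: str = "catmap",
) -> CategoryModel:
    """Fit transition/emission tables by Viterbi-EM over base segmentations."""
    if n_em_iters < 1:
        raise ValueError("n_em_iters must be >= 1")
    missing = [w for w in corpus.entries if w not in base.segmentations]
    if missing:
        raise ValueError(
            "base model was not trained on this corpus "
            f"(missing {len(missing)} words, e.g. {missing[:3]})"
        )

    prefs = _initial_categories(base)

    # initial hard assignment respecting the forbidden transitions
    def initial_path(ms: tuple[str, ...]) -> tuple[str, ...]:
        if len(ms) == 1:
            return (STEM,)
        path = []
        for i, m in enumerate(ms):
            allowed = set(_STATES)
            if i == 0:
                allowed.discard(SUFFIX)
            if i == len(ms) - 1:
                allowed.discard(PREFIX)
            choice = next(c for c in prefs[m] + [STEM] if c in allowed)
            path.append(choice)
        if STEM not in path:
            # anchor at the longest morph
            j = max(range(len(ms)), key=lambda i: (len(ms[i]), -i))
            path[j] = STEM
        return tuple(path)

    assignments = {
        w: initial_path(base.segmentations[w].morphs) for w in corpus.entries
    }

    model = None
    for _ in range(n_em_iters):
        model = _m_step(corpus, base, assignments, name)
        changed = False
        for w in corpus.entries:
            got = model.viterbi_path(base.segmentations[w].morphs)
            if got is None:
                continue
            path = got[0]
            if path != assignments[w]:
                assignments[w] = path
                changed = True
        if not changed:
            break
    return _m_step(corpus, base, assignments, name)


def _m_step(
    corpus: TokenCounts,
    base: MorfessorModel,
    assignments: dict[str, tuple[str, ...]],
    name: str,
) -> CategoryModel:
    t_counts: dict[tuple[str, str], float] = {}
    e_counts: dict[str, dict[str, float]] = {s: {} for s in _STATES}
    for w, path in assignments.items():
        cnt = corpus.entries[w]
        ms = base.segmentations[w].morphs
        prev = START
        for cat, m in zip(path, ms):
            t_counts[(prev, cat)] = t_counts.get((prev, cat), 0.0) + cnt
            e_counts[cat][m] = e_counts[cat].get(m, 0.0) + cnt
            prev = cat
        t_counts[(prev, END)] = t_counts.get((prev, END), 0.0) + cnt

    # add-0.5 smoothing, forbidden transitions pinned to zero, rows normalized
    transitions: dict[tuple[str, str], float] = {}
    for s0 in [START] + _STATES:
        targets = [s for s in _STATES + [END] if (s0, s) not in FORBIDDEN and s != START]
        raw = {s: t_counts.get((s0, s), 0.0) + 0.5 for s in targets}
        tot = sum(raw.values())
        for s in targets:
            transitions[(s0, s)] = raw[s] / tot
        for s in _STATES + [END]:
            if (s0, s) in FORBIDDEN:
                transitions[(s0, s)] = 0.0

    vocab = sorted(base.lexicon)
    emissions: dict[str, dict[str, float]] = {}
    floors: dict[str, float] = {}
    for s in _STATES:
        raw = {m: e_counts[s].get(m, 0.0) + 0.5 for m in vocab}
        tot = sum(raw.values())
        emissions[s] = {m: v / tot for m, v in raw.items()}
        floors[s] = 0.5 / tot
    return CategoryModel(
        transitions=transitions,
        emissions=emissions,
        base_segmenter=base,
        name=name,
        _em_floor=floors,
    )
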