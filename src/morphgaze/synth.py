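"""Synthetic agglutinative corpus, stimuli, and simulated gaze data.

This module stands in for everything the original study measured or
collected: a Zipfian agglutinative word-frequency corpus with known
("gold") morph segmentations, a 360-item stimulus set with an
oversampled high-frequency stratum, length-matched pseudowords from a
letter n-gram, and per-trial fixation data for the single-word
(lexical decision) and word-row designs with known effect structure —
separable "early" effects on first fixation duration and "late" effects
on gaze duration minus first fixation.

The generator is deliberately matched to the analysis model: measures
are linear-Gaussian in the predictors on the bit scale, with crossed
subject/item (and list) random intercepts, which is exactly the model
family the evaluation stage fits.  What it does not emulate: real
orthography/phonotactics, visual acuity, saccade targeting, or any
nonlinearity between surprisal and fixation times.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpusio import TokenCounts
from .gaze import FixationRecord, TrialRecord
from .ngram import LetterNgram
from .segmentation import Segmentation

logger = logging.getLogger(__name__)

_ALPHABET = "aehijklmnoprstuvy"
_VOWELS = "aeiouy"


# ---------------------------------------------------------------------------
# morphology grammar
# ---------------------------------------------------------------------------

@dataclass
class SuffixSlot:
    """One ordered suffix position with its inventory and attachment rate."""

    name: str
    morphs: list[str]
    attach_prob: float
    zipf: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.attach_prob <= 1.0:
            raise ValueError("attachment probability must be in [0, 1]")


@dataclass
class MorphologyGrammar:
    """Stem + ordered suffix slots; every generated word has 1-5 morphs.

    ``affinity`` controls stem-specific morphotactics: each stem gets its
    own preference order over every slot's inventory and its own
    attachment rate (Beta-distributed around the slot mean, concentration
    ``affinity_conc``).  This is what makes upcoming morphs genuinely
    predictable from the previous one — with fully independent slots the
    transition probabilities collapse onto the marginals and a bigram
    over morphs carries almost no information beyond a unigram.
    """

    stems: list[str]
    slots: list[SuffixSlot]
    stem_zipf: float = 1.0
    alphabet: str = _ALPHABET
    seed: int = 0
    affinity: bool = True
    affinity_conc: float = 6.0

    def __post_init__(self) -> None:
        if len(self.slots) > 4:
            raise ValueError("at most four suffix slots (1-5 morphs per word)")

    @classmethod
    def default(cls, seed: int = 0, n_stems: int = 420) -> "MorphologyGrammar":
        """The default grammar: 420 Zipfian stems (exponent 0.85) and four
        suffix slots (derivational, inflectional, possessive, clitic).

        The inventory sizes, attachment rates and the flattened stem
        exponent are chosen so that a desk-scale token sample reproduces
        the statistical regime of a large agglutinative corpus: a broad
        1-5 morphs-per-word range, suffixes that are short and far more
        frequent than any single word form, and enough token mass on
        tail stems that their word forms are not dominated by hapaxes.
        """
        rng = np.random.default_rng(seed)
        stems = _sample_morph_inventory(rng, n_stems, (4, 7))
        used = set(stems)
        slot_cfg = [
            ("derivational", 10, 0.30, (2, 4)),
            ("inflectional", 14, 0.55, (2, 3)),
            ("possessive", 6, 0.12, (2, 3)),
            ("clitic", 5, 0.10, (2, 3)),
        ]
        slots = []
        for name, size, p, lens in slot_cfg:
            inv = _sample_morph_inventory(rng, size, lens, forbidden=used)
            used.update(inv)
            slots.append(SuffixSlot(name, inv, attach_prob=p))
        return cls(stems=stems, slots=slots, seed=seed, stem_zipf=0.8)


def _sample_morph_inventory(
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int],
    forbidden: set[str] | None = None,
) -> list[str]:
    """Pronounceable-ish unique strings: consonants and vowels alternate
    with high probability."""
    forbidden = set(forbidden or ())
    out: list[str] = []
    cons = [c for c in _ALPHABET if c not in _VOWELS]
    vows = [c for c in _ALPHABET if c in _VOWELS]
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 100_000:
            raise RuntimeError("could not build a unique morph inventory")
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        start_vowel = bool(rng.random() < 0.4)
        chars = []
        for i in range(length):
            vowel = (i % 2 == 0) == start_vowel
            if rng.random() < 0.15:
                vowel = not vowel
            chars.append(
                vows[int(rng.integers(len(vows)))]
                if vowel
                else cons[int(rng.integers(len(cons)))]
            )
        s = "".join(chars)
        if s not in forbidden and s not in out:
            out.append(s)
    return out


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    p = ranks ** (-exponent)
    return p / p.sum()


def sample_corpus(
    grammar: MorphologyGrammar,
    n_tokens: int = 90_000,
    seed: int | None = None,
) -> tuple[TokenCounts, dict[str, Segmentation]]:
    """Draw a token corpus from the grammar, with gold segmentations.

    Each token: a stem sampled with Zipfian probability, then each slot
    attaches with its (stem-specific, when affinity is on) probability,
    with the slot morph Zipf-distributed under the stem's preference
    order.  When distinct morph sequences collide on the same surface
    string (realistic in concatenative systems) the most frequent
    analysis becomes the gold one; collisions are logged.
    """
    if n_tokens < 10 * len(grammar.stems):
        raise ValueError("n_tokens must be at least 10 per stem")
    rng = np.random.default_rng(grammar.seed if seed is None else seed)
    n_stems = len(grammar.stems)
    stem_idx = rng.choice(
        n_stems,
        size=n_tokens,
        p=_zipf_probs(n_stems, grammar.stem_zipf),
    )

    attach_cols = []
    slot_cols = []
    for slot in grammar.slots:
        base = _zipf_probs(len(slot.morphs), slot.zipf)
        if grammar.affinity:
            # per-stem attachment rate around the slot mean
            k = grammar.affinity_conc
            p_mean = min(max(slot.attach_prob, 1e-6), 1 - 1e-6)
            stem_attach = rng.beta(p_mean * k, (1 - p_mean) * k, n_stems)
            # per-stem preference order over the slot inventory
            cdfs = np.empty((n_stems, len(slot.morphs)))
            for s in range(n_stems):
                perm = rng.permutation(len(slot.morphs))
                probs = np.empty_like(base)
                probs[perm] = base
                cdfs[s] = np.cumsum(probs)
            u_attach = rng.random(n_tokens)
            attach_cols.append(u_attach < stem_attach[stem_idx])
            u_pick = rng.random(n_tokens)
            rows = cdfs[stem_idx]
            slot_cols.append((rows < u_pick[:, None]).sum(axis=1))
        else:
            attach_cols.append(rng.random(n_tokens) < slot.attach_prob)
            slot_cols.append(
                rng.choice(len(slot.morphs), size=n_tokens, p=base)
            )
    if grammar.slots:
        attach = np.column_stack(attach_cols)
        slot_idx = np.column_stack(slot_cols)
    else:
        attach = np.zeros((n_tokens, 0), bool)
        slot_idx = np.zeros((n_tokens, 0), int)

    counts: dict[str, int] = {}
    analyses: dict[str, dict[tuple[str, ...], int]] = {}
    for t in range(n_tokens):
        morphs = [grammar.stems[stem_idx[t]]]
        for j, slot in enumerate(grammar.slots):
            if attach[t, j]:
                morphs.append(slot.morphs[slot_idx[t, j]])
        word = "".join(morphs)
        counts[word] = counts.get(word, 0) + 1
        key = tuple(morphs)
        analyses.setdefault(word, {}).setdefault(key, 0)
        analyses[word][key] += 1

    gold: dict[str, Segmentation] = {}
    n_collisions = 0
    for word, alts in analyses.items():
        if len(alts) > 1:
            n_collisions += 1
        best = max(alts.items(), key=lambda kv: (kv[1], kv[0]))
        gold[word] = Segmentation(word, best[0])
    if n_collisions:
        logger.info(
            "surface collisions in %d/%d types (gold = most frequent analysis)",
            n_collisions, len(gold),
        )
    return TokenCounts(counts), gold


# ---------------------------------------------------------------------------
# stimuli and pseudowords
# ---------------------------------------------------------------------------

@dataclass
class StimulusSet:
    targets: list[str]
    oversampled_highfreq: list[str]
    pseudowords: list[str]
    fillers: list[str] = field(default_factory=list)


def select_stimuli(
    corpus: TokenCounts,
    gold: Mapping[str, Segmentation],
    n_random: int = 300,
    n_highfreq: int = 60,
    seed: int = 0,
    min_count: int = 6,
) -> tuple[list[str], list[str]]:
    """Target words with distinct stems: a frequency-floored random draw
    plus an oversampled high-frequency stratum.

    Selection is two-stage, mirroring how recognition materials are
    assembled rather than a raw token sample: a stem is drawn with
    probability proportional to its token mass, then one of the stem's
    eligible word forms is drawn uniformly, which keeps inflected and
    derived forms represented instead of letting bare stems dominate.
    ``min_count`` is the eligibility floor: stimuli must be words a
    reader plausibly knows, and the desk-scale corpus tail is dominated
    by forms that at the original corpus scale would have had hundreds
    of occurrences.  ``n_highfreq`` draws are restricted to the top
    frequency quartile and claim their stems first; no two targets share
    a stem (gold first morph).
    """
    if len(corpus.entries) < 2000:
        raise ValueError("corpus vocabulary must have >= 2000 types")
    rng = np.random.default_rng(seed)
    eligible = sorted(
        w for w, c in corpus.entries.items() if c >= min_count
    )
    if len(eligible) < n_random + n_highfreq:
        raise ValueError("not enough words above the stimulus frequency floor")

    def stem_of(w: str) -> str:
        return gold[w].morphs[0] if w in gold else w

    forms_by_stem: dict[str, list[str]] = {}
    for w in eligible:
        forms_by_stem.setdefault(stem_of(w), []).append(w)
    stems = sorted(forms_by_stem)
    stem_mass = np.array(
        [sum(corpus.entries[w] for w in forms_by_stem[s]) for s in stems],
        dtype=float,
    )

    used_stems: set[str] = set()

    # the oversampled stratum claims its stems first: filling it from the
    # top quartile after 300 stems are taken would exhaust the frequent
    # stems at desk scale
    by_freq = sorted(eligible, key=lambda w: -corpus.entries[w])
    top_quartile = by_freq[: max(len(by_freq) // 4, n_highfreq)]
    highfreq: list[str] = []
    for i in rng.permutation(len(top_quartile)):
        w = top_quartile[i]
        s = stem_of(w)
        if s in used_stems:
            continue
        used_stems.add(s)
        highfreq.append(w)
        if len(highfreq) == n_highfreq:
            break
    else:
        raise ValueError("not enough unique stems for high-frequency stimuli")

    probs = stem_mass / stem_mass.sum()
    targets_random: list[str] = []
    for _ in range(200):
        for i in rng.choice(len(stems), size=4 * n_random, p=probs):
            s = stems[i]
            if s in used_stems:
                continue
            used_stems.add(s)
            # balance morphological composition: pick a morph-count class
            # uniformly among those the stem offers, then a form within it
            forms = forms_by_stem[s]
            by_nmorph: dict[int, list[str]] = {}
            for w in forms:
                by_nmorph.setdefault(len(gold[w].morphs), []).append(w)
            classes = sorted(by_nmorph)
            cls = classes[int(rng.integers(len(classes)))]
            pool = by_nmorph[cls]
            targets_random.append(pool[int(rng.integers(len(pool)))])
            if len(targets_random) == n_random:
                break
        if len(targets_random) == n_random:
            break
    else:
        raise ValueError("not enough unique stems for random stimuli")
    return targets_random + highfreq, highfreq


def generate_pseudowords(
    real_words: Sequence[str],
    lengths: Sequence[int] | None = None,
    order: int = 3,
    vocabulary: set[str] | None = None,
    seed: int = 0,
    max_tries: int = 2000,
) -> list[str]:
    """Letter n-gram pseudowords, length-matched to the targets.

    Trains an order-``order`` letter model (additive 0.1 smoothing) on
    the real word types and samples strings of the required lengths,
    rejecting anything in the vocabulary (or already produced).  Raises
    an error naming the length whose rejection budget is exhausted.
    """
    if not real_words:
        raise ValueError("real_words must be non-empty")
    lengths = list(lengths if lengths is not None else map(len, real_words))
    vocabulary = set(vocabulary if vocabulary is not None else real_words)
    model = LetterNgram(order=order, smoothing=0.1).fit(real_words)
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    for length in lengths:
        for _ in range(max_tries):
            cand = model.sample_word(length, rng)
            if cand not in vocabulary and cand not in seen:
                out.append(cand)
                seen.add(cand)
                break
        else:
            raise ValueError(
                f"rejection budget exhausted for pseudowords of length {length}"
            )
    return out


def make_stimulus_set(
    corpus: TokenCounts,
    gold: Mapping[str, Segmentation],
    seed: int = 0,
    n_fillers: int = 2000,
) -> StimulusSet:
    """360 targets (300 random + 60 high-frequency), matched pseudowords,
    and filler nouns for the word-row design."""
    targets, highfreq = select_stimuli(corpus, gold, seed=seed)
    pseudo = generate_pseudowords(
        targets,
        vocabulary=set(corpus.entries),
        seed=seed + 1,
    )
    rng = np.random.default_rng(seed + 2)
    pool = sorted(set(corpus.entries) - set(targets))
    fillers = [pool[i] for i in rng.choice(len(pool), size=min(n_fillers, len(pool)), replace=False)]
    return StimulusSet(
        targets=targets,
        oversampled_highfreq=highfreq,
        pseudowords=pseudo,
        fillers=fillers,
    )


# ---------------------------------------------------------------------------
# gaze simulation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Effect structure of the simulated eye-tracking data.

    ``beta_early`` scales the early predictor's effect on FFD and
    ``beta_late`` the late predictor's effect on GmF, both in ms per SD
    of the (standardized) predictor.  ``single_fixation_prob`` is the
    probability that a target receives exactly one first-run fixation
    (GmF missing): 0.02 in the single-word design and 0.37 in the
    word-row design, matching multi-fixation rates of 98% and 63%.
    """

    n_subjects: int = 24
    intercept_ffd: float = 244.0
    intercept_gmf: float = 537.0
    beta_early: float = 12.0
    beta_late: float = 30.0
    subject_sd: float = 30.0
    item_sd: float = 15.0
    list_sd: float = 5.0
    position_slope_sd: float = 10.0
    resid_sd_ffd: float = 60.0
    resid_sd_gmf: float = 150.0
    single_fixation_prob: float = 0.02
    order_slope: float = -6.0
    launch_slope: float = 8.0
    launch_mean: float = 3.0
    launch_sd: float = 1.5
    error_rate_alpha: float = 2.0
    error_rate_beta: float = 38.0
    rt_noise_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subject_sd", "item_sd", "list_sd", "position_slope_sd",
                     "resid_sd_ffd", "resid_sd_gmf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.single_fixation_prob <= 1.0:
            raise ValueError("single_fixation_prob must be in [0, 1]")


EXP2_DEFAULTS = dict(n_subjects=26, single_fixation_prob=0.37,
                     intercept_ffd=306.0, intercept_gmf=484.0)


def exp2_config(**overrides) -> SimConfig:
    kw = dict(EXP2_DEFAULTS)
    kw.update(overrides)
    return SimConfig(**kw)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def simulate_exp1(
    stimuli: Sequence[str],
    early_predictor: Mapping[str, float],
    late_predictor: Mapping[str, float],
    config: SimConfig | None = None,
) -> list[TrialRecord]:
    """Simulate the single-word lexical decision design.

    Per subject x item: FFD gets the early effect, GmF the late effect,
    GD = FFD + GmF (or FFD when GmF is missing), and RT tracks GD with a
    small noise term so that corr(RT, GD) is approximately 0.99.  Each
    trial emits a fixation list from which the measures round-trip
    exactly (one fixation of FFD ms, plus one of GmF ms unless missing).
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    items = list(stimuli)
    missing_pred = [w for w in items if w not in early_predictor
                    or w not in late_predictor]
    if missing_pred:
        raise ValueError(f"predictors missing for items: {missing_pred[:5]}")
    x_early = _standardize(np.array([early_predictor[w] for w in items]))
    x_late = _standardize(np.array([late_predictor[w] for w in items]))

    n_s, n_i = cfg.n_subjects, len(items)
    u_subj = rng.normal(0.0, cfg.subject_sd, n_s)
    u_item_f = rng.normal(0.0, cfg.item_sd, n_i)
    u_item_g = rng.normal(0.0, cfg.item_sd, n_i)
    err_rates = rng.beta(cfg.error_rate_alpha, cfg.error_rate_beta, n_s)

    trials: list[TrialRecord] = []
    gd_all: list[float] = []
    for s in range(n_s):
        order = rng.permutation(n_i)
        order_pos = np.empty(n_i, int)
        order_pos[order] = np.arange(1, n_i + 1)
        z_order = _standardize(order_pos.astype(float))
        for i in range(n_i):
            ffd = (cfg.intercept_ffd + cfg.beta_early * x_early[i]
                   + u_subj[s] + u_item_f[i]
                   + cfg.order_slope * z_order[i]
                   + rng.normal(0.0, cfg.resid_sd_ffd))
            ffd = float(round(max(ffd, 30.0)))
            single = rng.random() < cfg.single_fixation_prob
            gmf = math.nan
            if not single:
                gmf = (cfg.intercept_gmf + cfg.beta_late * x_late[i]
                       + u_subj[s] + u_item_g[i]
                       + cfg.order_slope * z_order[i]
                       + rng.normal(0.0, cfg.resid_sd_gmf))
                gmf = float(round(max(gmf, 30.0)))
            gd = ffd if single else ffd + gmf
            gd_all.append(gd)
            fixes = [FixationRecord(f"s{s}", f"s{s}_{items[i]}", 1, 1,
                                    0.0, ffd)]
            if not single:
                fixes.append(FixationRecord(f"s{s}", f"s{s}_{items[i]}", 2, 1,
                                            ffd, gmf))
            correct = bool(rng.random() >= err_rates[s])
            trials.append(TrialRecord(
                subject=f"s{s}", item=items[i], fixations=fixes,
                presentation_order=int(order_pos[i]),
                response_correct=correct,
                rt_ms=gd,  # noise added below, needs global GD spread
            ))
    gd_arr = np.array(gd_all)
    rt_noise_sd = cfg.rt_noise_frac * gd_arr.std(ddof=0)
    for t in trials:
        t.rt_ms = float(t.rt_ms + rng.normal(0.0, rt_noise_sd))
    return trials


def build_rows(
    targets: Sequence[str],
    fillers: Sequence[str],
    pseudowords: Sequence[str],
    n_lists: int = 4,
    seed: int = 0,
) -> dict[str, list[dict]]:
    """Word rows for the multi-word design, per pseudorandomized list.

    Each list holds 180 target rows of seven words with targets at
    positions 3 and 5 (word-to-row assignment shuffled between lists)
    plus 180 pseudoword rows (one pseudoword at a balanced position).
    """
    targets = list(targets)
    if len(targets) % 2:
        raise ValueError("need an even number of targets (two per row)")
    n_rows = len(targets) // 2
    if len(fillers) < 5 * n_rows + 6:
        raise ValueError("not enough fillers to fill the target rows")
    if len(pseudowords) < 1:
        raise ValueError("need at least one pseudoword")
    rng = np.random.default_rng(seed)
    lists: dict[str, list[dict]] = {}
    for li in range(n_lists):
        order = rng.permutation(len(targets))
        rows = []
        for r in range(n_rows):
            t1, t2 = targets[order[2 * r]], targets[order[2 * r + 1]]
            fill = [fillers[int(i)] for i in
                    rng.choice(len(fillers), size=5, replace=False)]
            words = [fill[0], fill[1], t1, fill[2], t2, fill[3], fill[4]]
            rows.append({"words": words, "targets": {3: t1, 5: t2},
                         "has_pseudoword": False})
        for r in range(n_rows):
            pw = pseudowords[int(rng.integers(len(pseudowords)))]
            pos = 1 + (r % 7)
            fill = [fillers[int(i)] for i in
                    rng.choice(len(fillers), size=7, replace=False)]
            words = list(fill)
            words[pos - 1] = pw
            rows.append({"words": words, "targets": {},
                         "has_pseudoword": True})
        lists[f"list{li}"] = rows
    return lists


def simulate_exp2(
    stimuli: Sequence[str],
    fillers: Sequence[str],
    early_predictor: Mapping[str, float],
    late_predictor: Mapping[str, float],
    config: SimConfig | None = None,
    pseudowords: Sequence[str] | None = None,
) -> list[TrialRecord]:
    """Simulate the word-row design (targets at areas 3 and 5).

    One trial record per target occurrence, carrying the launch fixation
    in the preceding area followed by the target's first-run fixations,
    so the measure computation recovers FFD/GD/GmF and the launch site
    exactly.  Adds list random intercepts and a per-subject slope for
    the target's position in the row.
    """
    cfg = config or exp2_config()
    rng = np.random.default_rng(cfg.seed)
    items = list(stimuli)
    x_early = _standardize(np.array([early_predictor[w] for w in items]))
    x_late = _standardize(np.array([late_predictor[w] for w in items]))
    item_ix = {w: i for i, w in enumerate(items)}

    pseudo = list(pseudowords) if pseudowords is not None else ["zzzz"]
    lists = build_rows(items, list(fillers), pseudo, seed=cfg.seed)
    list_names = sorted(lists)
    u_list = {nm: rng.normal(0.0, cfg.list_sd) for nm in list_names}

    n_s = cfg.n_subjects
    u_subj = rng.normal(0.0, cfg.subject_sd, n_s)
    pos_slope = rng.normal(0.0, cfg.position_slope_sd, n_s)
    u_item_f = rng.normal(0.0, cfg.item_sd, len(items))
    u_item_g = rng.normal(0.0, cfg.item_sd, len(items))

    trials: list[TrialRecord] = []
    for s in range(n_s):
        list_id = list_names[s % len(list_names)]
        target_rows = [r for r in lists[list_id] if r["targets"]]
        row_order = rng.permutation(len(target_rows))
        n_total = 2 * len(target_rows)
        z_orders = _standardize(np.arange(1, n_total + 1, dtype=float))
        k = 0
        for ri in row_order:
            row = target_rows[ri]
            for area in (3, 5):
                w = row["targets"][area]
                i = item_ix[w]
                pos_coded = 0.5 if area == 5 else -0.5
                launch = max(rng.normal(cfg.launch_mean, cfg.launch_sd), 0.2)
                z_o = z_orders[k]
                ffd = (cfg.intercept_ffd + cfg.beta_early * x_early[i]
                       + u_subj[s] + u_item_f[i] + u_list[list_id]
                       + cfg.order_slope * z_o
                       + pos_slope[s] * pos_coded
                       + cfg.launch_slope * launch
                       + rng.normal(0.0, cfg.resid_sd_ffd))
                ffd = float(round(max(ffd, 30.0)))
                single = rng.random() < cfg.single_fixation_prob
                gmf = math.nan
                if not single:
                    gmf = (cfg.intercept_gmf + cfg.beta_late * x_late[i]
                           + u_subj[s] + u_item_g[i] + u_list[list_id]
                           + cfg.order_slope * z_o
                           + pos_slope[s] * pos_coded
                           + cfg.launch_slope * launch
                           + rng.normal(0.0, cfg.resid_sd_gmf))
                    gmf = float(round(max(gmf, 30.0)))
                trial_id = f"s{s}_r{ri}_a{area}"
                fixes = [
                    # launch fixation in the previous interest area
                    FixationRecord(f"s{s}", trial_id, 1, area - 1, 0.0,
                                   200.0, x_offset_letters=-launch),
                    FixationRecord(f"s{s}", trial_id, 2, area, 200.0, ffd,
                                   x_offset_letters=1.0),
                ]
                if not single:
                    fixes.append(FixationRecord(
                        f"s{s}", trial_id, 3, area, 200.0 + ffd, gmf,
                        x_offset_letters=3.0,
                    ))
                # leave the area (ends the first run)
                fixes.append(FixationRecord(
                    f"s{s}", trial_id, len(fixes) + 1, area + 1,
                    200.0 + ffd + (0.0 if single else gmf), 200.0,
                    x_offset_letters=1.0,
                ))
                k += 1
                trials.append(TrialRecord(
                    subject=f"s{s}", item=w, fixations=fixes,
                    presentation_order=k,
                    list_id=list_id, row_position=area,
                ))
    return trials
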