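# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `morphgaze`, in the spirit of a model reference
rather than a tutorial.

## The seven language models

All models assign a word `w` a self-information (surprisal)
`I(w) = -log2 P(w)` in bits; cross-entropy over a stimulus set is the
arithmetic mean of per-word self-information, computed through the same
code path (`morphgaze.surprisal`), so the identity between the two is
exact by construction.

| model | units | context | training |
|---|---|---|---|
| word unigram | surface forms | none | ML over token frequencies |
| MDL segmentation, alpha ∈ {0.01, 0.8, 10} | statistical morphs | none | unsupervised, see below |
| category HMM ("CatMAP" variant) | statistical morphs | category of previous morph | Viterbi-EM over the alpha = 0.01 segmentations |
| morph unigram | gold morphs | none | ML over pre-segmented input |
| morph bigram | gold morphs | previous morph | interpolated absolute discounting |

### MDL segmentation model

The model stores a lexicon of morphs and one segmentation per training
word, and minimizes the two-part cost

```
total = lexicon_cost + alpha * corpus_cost
lexicon_cost = sum over morph types of the letter-code length of the
               morph string (fixed letter distribution + end marker)
corpus_cost  = sum over morph tokens of -log2 c_m/N
             = N log2 N - sum_m c_m log2 c_m
```

`alpha > 0` is the corpus weight. A small `alpha` makes lexicon storage
dominant, favouring a compact inventory of short, reusable units; a
large `alpha` makes the encoding of the corpus dominant, which is
minimized by whole-word units (one token per occurrence). The letter
distribution is estimated once from the corpus (type-weighted letter
counts plus one end marker per type, add-one smoothed) and held fixed
during training.

**Search.** Training is coordinate descent over words: a word's current
morphs are removed, candidate segmentations are scored on the *exact*
incremental cost, and the best (or the incumbent, on ties) is restored,
so the accepted cost never increases. Words up to 6 letters are
enumerated exhaustively (`2^(L-1)` candidates); longer words get a
dynamic-programming proposal in which each candidate morph is charged
its approximate marginal cost independently. After every word pass, a
*lexicon refinement* pass applies three global move families over the
shared substructure, each accepted only on an exact cost decrease:
resplitting a lexicon morph everywhere it occurs, peeling a shared
suffix or prefix off all morphs that carry it in one joint move, and
merging an adjacent morph pair everywhere it occurs. These moves let
the model pay a new unit's lexicon cost once and amortize it over every
word containing it; without them, coordinate descent entrenches
frequent stem+suffix words as pseudo-stems and cannot coordinate
boundary changes across words. Epochs stop when the relative cost
decrease falls below `convergence_tol` (default 1e-4) or after
`max_epochs` (default 12; the model then carries `converged = False`).
Word order is shuffled per epoch under the run's seed; optional
restarts (`n_restarts`) guard against joint local minima on small
corpora — the first start is whole-word, the second fully letterized,
the rest random splits — with the lowest-cost final state retained. A
final deterministic sorted-order pass canonicalizes tie-broken
segmentations.

**Tie-break.** Among equal-cost analyses: fewer morphs first, then
leftmost-longest. The brute-force reference optimizer
(`exhaustive_optimum`) applies the same rule over words in sorted
order, and the test suite checks trainer/oracle equality on random toy
corpora.

**Scoring.** Stimulus words are re-analysed at scoring time by Viterbi
segmentation over the trained lexicon (maximum product of ML unigram
morph probabilities), rather than by lookup of the training-time
segmentation; the two coincide for training words at convergence in
practice, and re-analysis also covers unseen words. Out-of-vocabulary
morphs fall back to a letter-model probability scaled below any stored
morph; a strict mode marks such words unscorable instead.

### Category HMM

A flat HMM over the categories {prefix, stem, suffix, non-morpheme}
with word-start/word-end pseudo-states replaces the hierarchical
"CatMAP" lexicon: transitions `P(cat | prev cat)` and emissions
`P(morph | cat)` are estimated by Viterbi-EM (default 5 iterations,
add-0.5 smoothing) over the alpha = 0.01 segmentations, whose units are
close to gold morphs and make the categorical dependency meaningful.
Morphotactically impossible transitions (start→suffix, prefix→end) are
pinned to zero throughout, which among other things forces a
single-morph word out of the suffix and prefix categories. A word's
self-information is the negative log probability of its best category
path, including the boundary transitions.

### n-gram smoothing

The morph bigram uses interpolated absolute discounting with discount
0.5 over the ML unigram; rows sum to one over the event vocabulary
(including the word-end event), and unseen events after a seen context
receive discount mass times the unigram estimate. The unsmoothed ML
variants are retained for the oracle examples in the tests. The morph
unigram deliberately has no word-end event (it prices morph tokens
only), so the bigram's training-set advantage — checked in the tests —
comes from genuine context, net of its extra end-event cost.

## Eye-tracking measures

`FFD` is the duration of the first fixation on the target; `GD` the
summed fixation durations (single-word design) or the summed durations
of the *first run* — the maximal initial block of consecutive fixations
on the target (word-row design); `GmF = GD − FFD`, entered as missing
whenever the defining run has exactly one fixation. Trimming is
per-subject mean ± 3 sample SD (n−1), single pass, on reaction time in
the single-word design and first-run GD in the word-row design;
degenerate cases (SD 0, fewer than two rows) trim nothing. Error trials
are dropped first, then subjects whose error rate strictly exceeds 15%.
The short/long split is at ≤ 8 vs ≥ 9 letters.

The fixation report is a plain TSV (documented in `morphgaze.gaze`);
`x_offset_letters` is the signed letter offset of a fixation from the
left border of the *next* interest area, so the launch site — the
letter distance from the last fixation in the pre-target area to the
target's left border, positive for launches from the left — is
recoverable from the report alone, without a geometry side-table.

## Mixed models

All fits are maximum likelihood (not REML), because deviance and AIC
comparisons across different fixed-effect sets require it. The marginal
covariance is `sigma^2 (I + sum_k theta_k Z_k Z_k')` with one variance
ratio per random-effect block (subject, item, and for the word-row
design list intercepts and a per-subject slope of target position,
coded ±0.5). Fixed effects and the residual variance are profiled out
in closed form; the ratios are optimized by L-BFGS-B from `theta = 1`
starts with bounds `[0, 1e6]` and `ftol = 1e-10`, making fits
deterministic. All linear algebra runs in the random-effect coefficient
space (Woodbury identity), so a fit with ~400 crossed levels takes
milliseconds. Continuous covariates are standardized before fitting;
this stabilizes the optimizer and leaves deviance comparisons
unchanged. `AIC = deviance + 2k` with `k` = fixed effects + variance
ratios + residual.

Model comparison adds one surprisal column to the design-specific
baseline (single-word: presentation order; word-row: order + launch
site + the random structure above) and reports the deviance decrease
with a likelihood-ratio chi-square p-value at 1 df. Rows dropped for a
missing dependent (GmF on single-fixation trials) are dropped from that
measure's baseline too — never from the other measures — so compared
fits always share rows. The joint analysis moves the word unigram into
the baseline, making each model's delta its improvement beyond surface
frequency. Correlation tables are item-level (means over subjects)
Pearson r with stars at .05/.01/.001; constant columns report missing.

## Synthetic data

The generator replaces three unavailable inputs: the training corpus,
the stimulus materials, and the human gaze recordings.

**Corpus.** Words are stem + up to four ordered suffix slots
(derivational, inflectional, possessive, clitic), so every word has 1-5
morphs by construction. Defaults: 420 stems of 4-7 letters with Zipf
exponent 0.8; slot inventories 10/14/6/5 with attachment probabilities
.30/.55/.12/.10 and within-slot Zipf 0.8; 90k tokens. Morphotactics are
stem-specific by default (`affinity`): each stem carries its own
preference order over every slot's inventory and its own
Beta-distributed attachment rate around the slot mean. This is not a
cosmetic detail — with fully independent slots, morph transition
probabilities collapse onto the marginals, a bigram over morphs
correlates ~0.99 with the word unigram on the stimulus set, and no
context-sensitive model could be distinguished from a frequency model
by any analysis; stem-specific preferences are also what real
agglutinative paradigms look like. These values were
fixed by design analysis before the test suite was frozen. Two
desk-scale regime constraints drove them. First, the stem inventory
must exceed the 360 distinct stems the stimulus design consumes, and
every stem needs enough token mass that the lexicon term does not
fragment it at the smallest corpus weight (a first draft with
single-letter suffixes and a steeper stem law sat in a hapax-dominated
regime where it did). Second, whether the MDL optimum keeps a word
whole at alpha = 10 compares the stem+suffix surprisal with
`log2(N / count)`; this threshold depends on absolute counts, so a
corpus thousands of times smaller than the original cannot keep *both*
the relative frequency spectrum and the split behaviour of the original
— the defaults favour reproducing the alpha behaviour on the stimulus
words. Surface collisions between distinct morph sequences are allowed
(the most frequent analysis becomes gold) and logged.

**Stimuli.** Selection is two-stage, mirroring materials assembly
rather than raw token sampling: a stem is drawn with probability
proportional to its token mass, then one word form is drawn uniformly
over the stem's available morph-count classes, subject to a frequency
floor (`min_count = 6`) — recognition stimuli must be words a reader
plausibly knows, and at desk scale the corpus tail is dominated by
forms that at the original scale would have had hundreds of
occurrences. The 60-word high-frequency stratum is drawn from the top
frequency quartile and claims its stems first; no two targets share a
stem. One honest consequence of desk scale: stimulus morph counts span
1-3 (corpus types still span 1-5), narrower than a full-scale corpus
would support. 360 pseudowords come from an order-3 letter n-gram
(additive 0.1 smoothing), rejection-sampled to match the targets'
length multiset and to avoid the corpus vocabulary; filler nouns for
the word-row design are drawn from the non-target vocabulary. The
word-row builder emits, per list (4 lists), 180 target rows of seven
words with targets at positions 3 and 5, plus 180 one-pseudoword rows
with balanced pseudoword position.

**Gaze simulation.** Measures are linear-Gaussian on the bit scale:
FFD carries the early effect (`beta_early`, default 12 ms/SD), GmF the
late effect (`beta_late`, default 30 ms/SD), both with crossed
subject/item intercepts (SDs 30/15 ms), an order slope, and for the
word-row design list intercepts, a per-subject position slope (SD
10 ms) and a launch-site effect (8 ms/letter, launch ~ N(3, 1.5)
letters). GmF is missing with probability 0.02 (single-word) or 0.37
(word-row), the single-fixation rates implied by 98%/63% multi-fixation
observations; GD = FFD + GmF (or FFD alone); in the single-word design
RT = GD plus noise scaled to 15% of the GD spread, giving
corr(RT, GD) ≈ 0.99, and per-subject error rates are Beta(2, 38)
(mean 5%, occasionally above the 15% exclusion cap, so the exclusion
path is exercised). Durations are rounded to whole milliseconds so the
emitted fixation lists round-trip through the measure computation
*exactly*. Intercepts (244/537 ms single-word, 306/484 ms word-row)
follow the descriptive scale of the measures.

What the generator does not emulate: real phonotactics or orthography,
visual acuity and saccade-targeting constraints, refixation dynamics
beyond the first run, nonlinear (e.g. log-normal) duration
distributions, and any divergence between the generating model family
and the fitted one. Passing recovery tests therefore demonstrates the
pipeline's internal consistency and statistical calibration, not that
the models fit human data.

## Problem sizes in the tests

The suite trains on the default 100k-token corpus (tens of seconds per
alpha setting), uses 10 grammar seeds for the alpha-ordering check, 25
toy corpora for trainer/oracle equality, 500 replicates for the null
chi-square calibration, 100 for slope recovery, and 20 for the
early/late dissociation, with 8-12 simulated subjects where full-size
designs are not needed. These sizes were chosen so the whole suite runs
in well under half an hour on one CPU while keeping every statistical
check at the stated replicate counts.

## Known limitations

- The trainer is a local-search procedure; equality with the global
  cost minimizer is guaranteed only empirically, on small corpora, with
  restarts.
- The category HMM is a flat simplification; it shares the baseline
  model's segmentations rather than learning its own, and its
  categories are induced, not validated against linguistic labels.
- The mixed-model engine supports independent variance components
  (random intercepts and uncorrelated slopes), not correlated
  slope/intercept pairs or by-item slopes.
- Surprisal effects are injected and fitted on the same (linear, bit)
  scale; the package does not address functional-form questions.
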