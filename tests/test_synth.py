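"""Synthetic corpus, stimulus, pseudoword and gaze-data generators."""

import math

import numpy as np
import pandas as pd
import pytest

from morphgaze.gaze import measures_table
from morphgaze.synth import (
    MorphologyGrammar, SimConfig, SuffixSlot, build_rows, exp2_config,
    generate_pseudowords, make_stimulus_set, sample_corpus, select_stimuli,
    simulate_exp1, simulate_exp2,
)


def _grammar(**kw):
    g = MorphologyGrammar.default(seed=9)
    for slot in g.slots:
        if "attach" in kw:
            slot.attach_prob = kw["attach"]
    return g


class TestSampleCorpus:
    def test_no_attachment_means_monomorphemic(self):
        g = _grammar(attach=0.0)
        corpus, gold = sample_corpus(g, n_tokens=5000)
        assert all(len(s.morphs) == 1 for s in gold.values())

    def test_full_attachment_means_five_morphs(self):
        g = _grammar(attach=1.0)
        corpus, gold = sample_corpus(g, n_tokens=5000)
        assert all(len(s.morphs) == 5 for s in gold.values())

    def test_gold_concatenates(self, default_corpus):
        corpus, gold = default_corpus
        assert set(gold) == set(corpus.entries)
        for w, seg in gold.items():
            assert "".join(seg.morphs) == w

    def test_morph_range_spans_one_to_five(self, default_corpus):
        _, gold = default_corpus
        lens = {len(s.morphs) for s in gold.values()}
        assert lens == {1, 2, 3, 4, 5}

    def test_zipf_exponent_recovered(self):
        """Stem frequency rank-slope close to the configured exponent."""
        g = MorphologyGrammar.default(seed=2)
        corpus, gold = sample_corpus(g, n_tokens=200_000)
        stem_counts: dict[str, int] = {}
        for w, c in corpus.entries.items():
            s = gold[w].morphs[0]
            stem_counts[s] = stem_counts.get(s, 0) + c
        counts = np.sort(np.array(list(stem_counts.values())))[::-1]
        top = counts[: len(counts) // 2]  # tail ranks distorted by sampling
        ranks = np.arange(1, len(top) + 1)
        slope = np.polyfit(np.log(ranks), np.log(top), 1)[0]
        assert -slope == pytest.approx(g.stem_zipf, abs=0.15)

    def test_determinism(self):
        g = MorphologyGrammar.default(seed=4)
        c1, g1 = sample_corpus(g, n_tokens=20_000)
        c2, g2 = sample_corpus(g, n_tokens=20_000)
        assert c1.entries == c2.entries
        assert {w: s.morphs for w, s in g1.items()} == {
            w: s.morphs for w, s in g2.items()
        }

    def test_token_minimum_enforced(self):
        with pytest.raises(ValueError):
            sample_corpus(MorphologyGrammar.default(), n_tokens=100)


class TestStimuli:
    def test_counts(self, default_stimuli):
        assert len(default_stimuli.targets) == 360
        assert len(default_stimuli.oversampled_highfreq) == 60
        assert len(default_stimuli.pseudowords) == 360

    def test_no_shared_stems(self, default_corpus):
        corpus, gold = default_corpus
        targets, _ = select_stimuli(corpus, gold, seed=3)
        stems = [gold[w].morphs[0] for w in targets]
        assert len(set(stems)) == len(stems)

    def test_deterministic_given_seed(self, default_corpus):
        corpus, gold = default_corpus
        t1, _ = select_stimuli(corpus, gold, seed=5)
        t2, _ = select_stimuli(corpus, gold, seed=5)
        assert t1 == t2

    def test_small_vocabulary_rejected(self):
        g = _grammar(attach=0.0)
        corpus, gold = sample_corpus(g, n_tokens=5000)
        with pytest.raises(ValueError):
            select_stimuli(corpus, gold)

    def test_highfreq_stratum_is_high_frequency(self, default_corpus,
                                                default_stimuli):
        corpus, _ = default_corpus
        counts = sorted(corpus.entries.values(), reverse=True)
        quartile_floor = counts[len(counts) // 4]
        got = [corpus.entries[w]
               for w in default_stimuli.oversampled_highfreq]
        assert min(got) >= quartile_floor


class TestPseudowords:
    def test_not_in_vocabulary_and_length_matched(self, default_corpus,
                                                  default_stimuli):
        corpus, _ = default_corpus
        pseudo = default_stimuli.pseudowords
        assert not set(pseudo) & set(corpus.entries)
        assert sorted(map(len, pseudo)) == sorted(
            map(len, default_stimuli.targets)
        )

    def test_impossible_lengths_raise(self):
        # a unigram model over a one-letter alphabet can only emit "aaa..."
        with pytest.raises(ValueError, match="length 3"):
            generate_pseudowords(
                ["aaa"], lengths=[3], order=1, vocabulary={"aaa"},
            )


class TestSimulateExp1:
    def test_deterministic_limit(self, rng):
        """All noise off: FFD is exactly intercept + beta * standardized X."""
        cfg = SimConfig(
            n_subjects=2, subject_sd=0, item_sd=0, resid_sd_ffd=0,
            resid_sd_gmf=0, order_slope=0, single_fixation_prob=0,
            beta_early=1.0, rt_noise_frac=0, seed=0,
        )
        # two items, standardized X = (-1, +1)
        trials = simulate_exp1(
            ["aa", "bb"], {"aa": 1.0, "bb": 3.0}, {"aa": 1.0, "bb": 3.0}, cfg
        )
        ffd = {t.item: t.fixations[0].duration for t in trials}
        assert ffd["aa"] == cfg.intercept_ffd - 1.0
        assert ffd["bb"] == cfg.intercept_ffd + 1.0

    def test_missing_gmf_fraction_binomial(self, default_stimuli,
                                           stimulus_surprisals):
        early = stimulus_surprisals["morph_unigram"].values
        late = stimulus_surprisals["morph_bigram"].values
        # pool several simulated datasets so the binomial check runs at a
        # sample size where 2 SE is a meaningful band
        n = miss = 0
        for seed in (11, 12, 13):
            trials = simulate_exp1(default_stimuli.targets, early, late,
                                   SimConfig(seed=seed))
            meas = measures_table(trials, "exp1")
            miss += meas["GmF"].isna().sum()
            n += len(meas)
        se = math.sqrt(0.02 * 0.98 / n)
        assert abs(miss / n - 0.02) <= 2 * se

    def test_rt_tracks_gd(self, default_stimuli, stimulus_surprisals):
        early = stimulus_surprisals["morph_unigram"].values
        late = stimulus_surprisals["morph_bigram"].values
        trials = simulate_exp1(default_stimuli.targets, early, late,
                               SimConfig(seed=3))
        meas = measures_table(trials, "exp1")
        r = np.corrcoef(meas["GD"], meas["rt_ms"])[0, 1]
        assert r >= 0.98

    def test_roundtrip_exact(self, default_stimuli, stimulus_surprisals):
        """Measures computed from the emitted fixations equal the simulated
        values exactly."""
        early = stimulus_surprisals["morph_unigram"].values
        trials = simulate_exp1(default_stimuli.targets[:50], early, early,
                               SimConfig(n_subjects=3, seed=7))
        meas = measures_table(trials, "exp1")
        for t, (_, row) in zip(trials, meas.iterrows()):
            durs = [f.duration for f in t.fixations]
            assert row["FFD"] == durs[0]
            assert row["GD"] == sum(durs)
            if len(durs) > 1:
                assert row["GmF"] == sum(durs) - durs[0]


@pytest.fixture(scope="module")
def exp2_trials(default_stimuli, stimulus_surprisals):
    early = stimulus_surprisals["morph_unigram"].values
    late = stimulus_surprisals["morph_bigram"].values
    return simulate_exp2(
        default_stimuli.targets, default_stimuli.fillers, early, late,
        exp2_config(n_subjects=6, seed=21),
        pseudowords=default_stimuli.pseudowords,
    )


class TestSimulateExp2:
    def test_rows_have_seven_words_targets_at_3_and_5(self, default_stimuli):
        lists = build_rows(default_stimuli.targets, default_stimuli.fillers,
                           default_stimuli.pseudowords, seed=0)
        assert len(lists) == 4
        for rows in lists.values():
            target_rows = [r for r in rows if r["targets"]]
            assert len(target_rows) == 180
            pseudo_rows = [r for r in rows if r["has_pseudoword"]]
            assert len(pseudo_rows) == 180
            for r in rows:
                assert len(r["words"]) == 7
            for r in target_rows:
                assert set(r["targets"]) == {3, 5}
                assert r["words"][2] == r["targets"][3]
                assert r["words"][4] == r["targets"][5]

    def test_roundtrip_gd_exact(self, exp2_trials):
        meas = measures_table(exp2_trials, "exp2")
        for t, (_, row) in zip(exp2_trials, meas.iterrows()):
            run = [f.duration for f in t.fixations
                   if f.interest_area == t.row_position]
            assert row["GD"] == sum(run)
            assert row["FFD"] == run[0]

    def test_missing_gmf_fraction(self, exp2_trials):
        meas = measures_table(exp2_trials, "exp2")
        frac = meas["GmF"].isna().mean()
        se = math.sqrt(0.37 * 0.63 / len(meas))
        assert abs(frac - 0.37) <= 2 * se

    def test_launch_site_recovered(self, exp2_trials):
        meas = measures_table(exp2_trials, "exp2")
        assert meas["launch_site"].notna().all()
        assert (meas["launch_site"] > 0).all()

    def test_filler_shortage_raises(self, default_stimuli):
        with pytest.raises(ValueError, match="fillers"):
            build_rows(default_stimuli.targets, ["only", "four", "filler",
                                                 "words"],
                       default_stimuli.pseudowords)
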