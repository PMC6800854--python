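"""Shared fixtures: the default synthetic corpus and trained models.

The expensive session fixtures (default corpus, the three MDL trainings,
the full seven-model set) are shared across the unit and acceptance
tests so each is built exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from morphgaze.corpusio import TokenCounts
from morphgaze.morfessor import MorfessorParams, train_morfessor_baseline
from morphgaze.surprisal import score_words
from morphgaze.synth import MorphologyGrammar, make_stimulus_set, sample_corpus

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_corpus():
    """Default synthetic corpus (seed 0) with gold segmentations."""
    grammar = MorphologyGrammar.default(seed=0)
    corpus, gold = sample_corpus(grammar)
    return corpus, gold


@pytest.fixture(scope="session")
def default_stimuli(default_corpus):
    corpus, gold = default_corpus
    return make_stimulus_set(corpus, gold, seed=0)


@pytest.fixture(scope="session")
def mdl_models(default_corpus):
    """MDL segmentation models at the three alpha settings, seed 0."""
    corpus, _gold = default_corpus
    return {
        a: train_morfessor_baseline(corpus, MorfessorParams(alpha=a, seed=0))
        for a in (0.01, 0.8, 10.0)
    }


@pytest.fixture(scope="session")
def seven_models(default_corpus, mdl_models):
    """All seven language models trained on the default corpus."""
    from morphgaze.catmap import train_catmap
    from morphgaze.ngram import train_morph_ngram, train_word_unigram

    corpus, gold = default_corpus
    segmented = {w: (gold[w], c) for w, c in corpus.entries.items()}
    models = {
        "word_unigram": train_word_unigram(corpus),
        "morph_unigram": train_morph_ngram(segmented, order=1),
        "morph_bigram": train_morph_ngram(segmented, order=2),
        "catmap": train_catmap(corpus, mdl_models[0.01]),
    }
    for a, m in mdl_models.items():
        models[f"morfessor_{a:g}"] = m
    return models


@pytest.fixture(scope="session")
def stimulus_surprisals(seven_models, default_stimuli):
    return {
        name: score_words(m, default_stimuli.targets)
        for name, m in seven_models.items()
    }


@pytest.fixture()
def tiny_corpus():
    return TokenCounts({"talo": 6, "talossa": 3, "autossa": 2, "auto": 4})


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
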