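"""End-to-end run: corpus -> models -> surprisals -> measures -> rankings.

One reproducible run generates (or ingests) the corpus, trains all seven
language models, scores the stimuli, computes the eye-tracking measures
for both designs, and writes the full-set, length-split and joint
analyses as TSV + JSON, together with a cross-entropy table and a run
manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .catmap import train_catmap
from .corpusio import (
    TokenCounts, save_corpus, save_segmentations, save_surprisals,
)
from .gaze import (
    exclude_error_and_subjects, measures_table, split_by_length,
    trim_outliers, write_fixation_report,
)
from .lmm import correlations, joint_with_word_unigram, run_model_ranking
from .morfessor import MorfessorParams, train_morfessor_baseline
from .ngram import train_morph_ngram, train_word_unigram
from .surprisal import cross_entropy, score_words
from .synth import (
    MorphologyGrammar, SimConfig, exp2_config, make_stimulus_set,
    sample_corpus, simulate_exp1, simulate_exp2,
)

logger = logging.getLogger(__name__)

MODEL_NAMES = (
    "word_unigram",
    "morfessor_0.01",
    "morfessor_0.8",
    "morfessor_10",
    "catmap",
    "morph_unigram",
    "morph_bigram",
)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "corpus": {"n_stems": 420, "n_tokens": 90_000, "min_count": 1},
    "models": list(MODEL_NAMES),
    "alphas": [0.01, 0.8, 10.0],
    "catmap_base_alpha": 0.01,
    "sim_exp1": {},
    "sim_exp2": {},
    "analyses": {"length_split": True, "joint_word_unigram": True,
                 "correlations": True},
    "true_predictors": {"early": "morph_unigram", "late": "morph_bigram"},
    "length_threshold": 8,
}


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    outputs: list[str] = field(default_factory=list)
    stages: dict[str, str] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _merge_config(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (config or {}).items():
        if k not in merged:
            raise ValueError(f"unknown config key {k!r}")
        if isinstance(merged[k], dict) and isinstance(v, dict):
            merged[k].update(v)
        else:
            merged[k] = v
    bad = set(merged["models"]) - set(MODEL_NAMES)
    if bad:
        raise ValueError(
            f"unknown model names {sorted(bad)}; valid: {list(MODEL_NAMES)}"
        )
    return merged


def train_all_models(
    corpus: TokenCounts,
    gold,
    seed: int = 0,
    alphas=(0.01, 0.8, 10.0),
    catmap_base_alpha: float = 0.01,
    model_names=MODEL_NAMES,
):
    """Train the seven language models; returns ``{name: model}``."""
    models: dict[str, Any] = {}
    segmented = {w: (gold[w], c) for w, c in corpus.entries.items()}
    morf: dict[float, Any] = {}
    for a in alphas:
        name = f"morfessor_{a:g}"
        if name in model_names:
            logger.info("training %s", name)
            morf[a] = train_morfessor_baseline(
                corpus, MorfessorParams(alpha=a, seed=seed), name=name
            )
            models[name] = morf[a]
    if "word_unigram" in model_names:
        models["word_unigram"] = train_word_unigram(corpus)
    if "morph_unigram" in model_names:
        models["morph_unigram"] = train_morph_ngram(segmented, order=1)
    if "morph_bigram" in model_names:
        models["morph_bigram"] = train_morph_ngram(segmented, order=2)
    if "catmap" in model_names:
        base = morf.get(catmap_base_alpha)
        if base is None:
            base = train_morfessor_baseline(
                corpus, MorfessorParams(alpha=catmap_base_alpha, seed=seed)
            )
        models["catmap"] = train_catmap(corpus, base)
    return models


def _write_rankings(rankings: dict[str, pd.DataFrame], out: Path,
                    stem: str, manifest: RunManifest) -> None:
    for measure, df in rankings.items():
        tsv = out / f"{stem}_{measure}.tsv"
        df.to_csv(tsv, sep="\t", index=False)
        manifest.outputs.append(tsv.name)
    js = out / f"{stem}.json"
    js.write_text(json.dumps(
        {m: df.to_dict(orient="records") for m, df in rankings.items()},
        indent=2,
    ))
    manifest.outputs.append(js.name)


def run_pipeline(
    config: dict | None, out_dir: str | Path, seed: int | None = None
) -> RunManifest:
    """Execute the full analysis; any stage failure aborts with its name."""
    cfg = _merge_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed, version=__version__)
    stage = "init"
    try:
        # -- corpus and stimuli ------------------------------------------
        stage = "corpus"
        grammar = MorphologyGrammar.default(
            seed=seed, n_stems=cfg["corpus"]["n_stems"]
        )
        corpus, gold = sample_corpus(grammar, cfg["corpus"]["n_tokens"])
        if cfg["corpus"]["min_count"] > 1:
            corpus = corpus.filtered(cfg["corpus"]["min_count"])
            gold = {w: gold[w] for w in corpus.entries}
        save_corpus(corpus, out / "corpus.tsv")
        save_segmentations(
            {w: s.morphs for w, s in gold.items()},
            out / "gold_segmentations.tsv",
        )
        manifest.outputs += ["corpus.tsv", "gold_segmentations.tsv"]
        manifest.stages[stage] = "ok"

        stage = "stimuli"
        stim = make_stimulus_set(corpus, gold, seed=seed)
        (out / "stimuli.txt").write_text("\n".join(stim.targets) + "\n")
        (out / "pseudowords.txt").write_text("\n".join(stim.pseudowords) + "\n")
        manifest.outputs += ["stimuli.txt", "pseudowords.txt"]
        manifest.stages[stage] = "ok"

        # -- models and surprisals ---------------------------------------
        stage = "train"
        models = train_all_models(
            corpus, gold, seed=seed, alphas=cfg["alphas"],
            catmap_base_alpha=cfg["catmap_base_alpha"],
            model_names=cfg["models"],
        )
        manifest.stages[stage] = "ok"

        stage = "score"
        surprisals = {
            name: score_words(m, stim.targets) for name, m in models.items()
        }
        for i, (name, vec) in enumerate(surprisals.items()):
            save_surprisals(vec.values, name, out / "surprisals.tsv",
                            append=i > 0)
        xent_rows = [
            {"model": name, "cross_entropy_bits": cross_entropy(m, stim.targets)}
            for name, m in models.items()
        ]
        pd.DataFrame(xent_rows).to_csv(
            out / "cross_entropy.tsv", sep="\t", index=False
        )
        manifest.outputs += ["surprisals.tsv", "cross_entropy.tsv"]
        manifest.stages[stage] = "ok"

        # -- simulated gaze data and measures ----------------------------
        stage = "simulate"
        early = surprisals[cfg["true_predictors"]["early"]].values
        late = surprisals[cfg["true_predictors"]["late"]].values
        sim1 = SimConfig(seed=seed + 11, **cfg["sim_exp1"])
        trials1 = simulate_exp1(stim.targets, early, late, sim1)
        sim2 = exp2_config(seed=seed + 13, **cfg["sim_exp2"])
        trials2 = simulate_exp2(
            stim.targets, stim.fillers, early, late, sim2,
            pseudowords=stim.pseudowords,
        )
        write_fixation_report(trials1, out / "fixations_exp1.tsv")
        write_fixation_report(trials2, out / "fixations_exp2.tsv")
        manifest.outputs += ["fixations_exp1.tsv", "fixations_exp2.tsv"]
        manifest.stages[stage] = "ok"

        stage = "measures"
        m1 = measures_table(trials1, "exp1")
        m1 = exclude_error_and_subjects(m1)
        m1 = trim_outliers(m1, "rt_ms")
        m2 = measures_table(trials2, "exp2")
        m2 = trim_outliers(m2, "GD")
        m1.to_csv(out / "measures_exp1.tsv", sep="\t", index=False)
        m2.to_csv(out / "measures_exp2.tsv", sep="\t", index=False)
        manifest.outputs += ["measures_exp1.tsv", "measures_exp2.tsv"]
        manifest.stages[stage] = "ok"

        # -- rankings -----------------------------------------------------
        stage = "rankings"
        for design, meas in (("exp1", m1), ("exp2", m2)):
            full = run_model_ranking(meas, surprisals, design)
            _write_rankings(full, out, f"ranking_{design}_full", manifest)
            if cfg["analyses"]["joint_word_unigram"]:
                joint = joint_with_word_unigram(meas, surprisals, design)
                _write_rankings(joint, out, f"ranking_{design}_joint", manifest)
            if cfg["analyses"]["length_split"]:
                short, long_ = split_by_length(
                    stim.targets, cfg["length_threshold"]
                )
                for label, group in (("short", short), ("long", long_)):
                    sub = meas[meas["item"].isin(group)]
                    ranked = run_model_ranking(sub, surprisals, design)
                    _write_rankings(
                        ranked, out, f"ranking_{design}_{label}", manifest
                    )
            if cfg["analyses"]["correlations"]:
                preds = pd.DataFrame(
                    {name: vec.values for name, vec in surprisals.items()}
                )
                preds["n_letters"] = [len(w) for w in preds.index]
                corr = correlations(meas, preds)
                corr.to_csv(
                    out / f"correlations_{design}.tsv", sep="\t", index=False
                )
                manifest.outputs.append(f"correlations_{design}.tsv")
        manifest.stages[stage] = "ok"
    except Exception as exc:
        manifest.stages[stage] = f"failed: {exc}"
        manifest.save(out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.save(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest
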