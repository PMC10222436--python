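"""Canonical end-to-end study protocols on synthetic corpora.

These fix the problem sizes the package's headline checks run at (chosen to
fit a single desktop CPU; see docs/methods.md):

* recovery: 1000 sentences with overlap mix 0.5/0.25/0.25 and 4 relations,
  split 800 train / 200 held-out, desk-scale model, 40 epochs.
* EPO ablation: an EPO-heavy mix 0.1/0.8/0.1, 400 sentences split 300/100,
  full model vs the plain multi-head-attention variant, identical seeds,
  median over 3 seeds.
"""

from __future__ import annotations

import numpy as np

from .api import TripletExtractor
from .evaluation import EPO, EvalReport
from .experiments import ablate
from .model import ModelConfig
from .synthetic import GeneratorConfig, default_schema, generate_corpus
from .training import TrainConfig

DESK_MODEL = ModelConfig(max_length=48)

RECOVERY_GENERATOR = dict(n_sentences=1000, class_mix=(0.5, 0.25, 0.25),
                          n_relations=4)
RECOVERY_SPLIT = 800
RECOVERY_EPOCHS = 40

ABLATION_GENERATOR = dict(n_sentences=400, class_mix=(0.1, 0.8, 0.1),
                          n_relations=4)
ABLATION_SPLIT = 300
ABLATION_EPOCHS = 25
ABLATION_SEEDS = 3


def end_to_end_recovery(seed: int) -> tuple[EvalReport, dict]:
    """Train on 800 synthetic sentences, score exact-match F1 on 200 held out.

    The held-out block is an untrained split of the same generated corpus
    (same entity lexicon, disjoint sentences).  Returns the evaluation report
    and the training history.
    """
    schema = default_schema(RECOVERY_GENERATOR["n_relations"])
    corpus = generate_corpus(
        GeneratorConfig(seed=seed, **RECOVERY_GENERATOR), schema)
    train_c, test_c = corpus[:RECOVERY_SPLIT], corpus[RECOVERY_SPLIT:]
    res = TripletExtractor(train_c, schema, DESK_MODEL).fit(
        TrainConfig(epochs=RECOVERY_EPOCHS, seed=seed))
    return res.evaluate(test_c, by_class=True), res.history


def epo_ablation(seed: int, n_seeds: int = ABLATION_SEEDS
                 ) -> tuple[float, float, list[tuple[float, float]]]:
    """Median EPO-class F1 of the full model vs the no-THA variant.

    Each replicate trains both variants on the same EPO-heavy corpus with the
    same seed.  Returns (median full, median no_tha, per-seed pairs).
    """
    schema = default_schema(ABLATION_GENERATOR["n_relations"])
    pairs: list[tuple[float, float]] = []
    for k in range(n_seeds):
        rep_seed = seed + 1000 * k
        corpus = generate_corpus(
            GeneratorConfig(seed=rep_seed, **ABLATION_GENERATOR), schema)
        reports = ablate(corpus[:ABLATION_SPLIT], corpus[ABLATION_SPLIT:],
                         schema, ["full", "no_tha"], DESK_MODEL,
                         TrainConfig(epochs=ABLATION_EPOCHS, seed=rep_seed))
        pairs.append((reports["full"].per_class[EPO].f1,
                      reports["no_tha"].per_class[EPO].f1))
    full = float(np.median([p[0] for p in pairs]))
    no_tha = float(np.median([p[1] for p in pairs]))
    return full, no_tha, pairs
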