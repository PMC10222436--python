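"""Experiment drivers: ablations and the talking-head head-count sweep.

``ablate`` retrains the model with one component removed at a time
(identical data and seed), mirroring the component-contribution analysis:
``no_cln`` replaces conditional layer normalization with unconditioned layer
norm, ``no_tha`` replaces talking-head attention with plain multi-head
attention, ``small_encoder`` halves the encoder depth.  ``head_sweep``
retrains with a range of talking-head counts.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

from .api import TripletExtractor
from .corpus import AnnotatedSentence, RelationSchema
from .evaluation import EvalReport
from .model import ModelConfig
from .training import TrainConfig

ABLATION_VARIANTS = ("full", "no_cln", "no_tha", "small_encoder")


class ExperimentConfigError(ValueError):
    pass


def _variant_config(base: ModelConfig, variant: str) -> ModelConfig:
    if variant == "full":
        return base
    if variant == "no_cln":
        return replace(base, use_cln=False)
    if variant == "no_tha":
        return replace(base, use_tha=False)
    if variant == "small_encoder":
        return replace(base, n_blocks=max(1, base.n_blocks // 2))
    raise ExperimentConfigError(
        f"unknown variant {variant!r}; choose from {ABLATION_VARIANTS}")


def ablate(train_corpus: Sequence[AnnotatedSentence],
           dev_corpus: Sequence[AnnotatedSentence],
           schema: RelationSchema,
           variants: Sequence[str],
           model_config: ModelConfig | None = None,
           train_config: TrainConfig | None = None) -> dict[str, EvalReport]:
    """Train each variant with identical seed/data; report dev exact-match scores."""
    if not variants:
        raise ExperimentConfigError("variant set must be non-empty")
    base = model_config or ModelConfig()
    tc = train_config or TrainConfig()
    reports: dict[str, EvalReport] = {}
    for variant in variants:
        cfg = _variant_config(base, variant)
        res = TripletExtractor(train_corpus, schema, cfg).fit(tc)
        reports[variant] = res.evaluate(dev_corpus, by_class=True)
    return reports


def head_sweep(train_corpus: Sequence[AnnotatedSentence],
               dev_corpus: Sequence[AnnotatedSentence],
               schema: RelationSchema,
               head_counts: Sequence[int],
               model_config: ModelConfig | None = None,
               train_config: TrainConfig | None = None
               ) -> list[tuple[int, float, float, float]]:
    """One seeded train/eval cycle per talking-head count.

    Returns rows (heads, precision, recall, f1); every head count must divide
    the hidden size.
    """
    base = model_config or ModelConfig()
    tc = train_config or TrainConfig()
    for h in head_counts:
        if h < 1 or base.hidden_size % h:
            raise ExperimentConfigError(
                f"head count {h} must divide hidden size {base.hidden_size}")
    rows = []
    for h in head_counts:
        cfg = replace(base, tha_heads=h)
        res = TripletExtractor(train_corpus, schema, cfg).fit(tc)
        rep = res.evaluate(dev_corpus, by_class=False)
        rows.append((h, rep.precision, rep.recall, rep.f1))
    return rows
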