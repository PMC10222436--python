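"""The cascade binary-tagging extraction model.

Stage 1 (subject extraction): a width-1 sigmoid pointer head over the encoder
features h marks, per token, the probability of being a subject start / end.

Stage 2 (relation-object extraction): for a chosen subject with span
representation v (mean of h over the span), the pipeline is

    h -> CLN(h; gamma(v), beta(v)) -> + position embeddings -> talking-head
    attention -> O -> sigmoid(W (O + v) + b)

yielding, per token, start/end probabilities for every relation r in the
schema (width R).  During training every gold subject of a sentence is
traversed (teacher forcing); at inference the stage-2 tagger is run once per
decoded subject.

The objective K is the summed Bernoulli log-likelihood of the gold start/end
tags of subjects and, per subject, of objects under every relation; training
maximises K (minimises -K).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._tensor import Tensor, clip, log, no_grad
from . import nn
from .corpus import AnnotatedSentence, RelationSchema
from .encoder import (EncodedSentence, Encoder, EncoderConfig, Vocabulary,
                      load_pretrained_adapter)
from .layers import (ConditionMaps, PointerHead, TalkingHeadWeights,
                     conditional_layer_norm, make_condition,
                     multi_head_attention, pointer_probabilities,
                     talking_head_attention)

LOSS_EPS = 1e-7  # probability clip inside the likelihood


@dataclass(frozen=True)
class ModelConfig:
    """Desk-scale defaults; the full-scale profile mirrors the original
    12-block / 768-wide / 48-head configuration."""

    hidden_size: int = 64
    n_blocks: int = 2
    n_encoder_heads: int = 4
    tha_heads: int = 8
    max_length: int = 128
    ffn_multiplier: int = 4
    dropout: float = 0.0
    cln_eps: float = 1e-6
    use_cln: bool = True    # False: unconditioned layer norm (ablation)
    use_tha: bool = True    # False: plain multi-head attention (ablation)
    pretrained: str | None = None

    @classmethod
    def full_scale(cls) -> "ModelConfig":
        return cls(hidden_size=768, n_blocks=12, n_encoder_heads=12,
                   tha_heads=48, max_length=128)

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(hidden_size=self.hidden_size, n_blocks=self.n_blocks,
                             n_encoder_heads=self.n_encoder_heads,
                             max_length=self.max_length,
                             ffn_multiplier=self.ffn_multiplier,
                             dropout=self.dropout, ln_eps=self.cln_eps,
                             pretrained=self.pretrained)


@dataclass(frozen=True)
class SubjectSpan:
    """Half-open token span of a decoded or gold subject."""

    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


class CascadeTagger:
    """Encoder + subject pointer head + conditioned relation-object tagger."""

    def __init__(self, config: ModelConfig, schema: RelationSchema,
                 vocab: Vocabulary, seed: int = 0):
        self.config = config
        self.schema = schema
        rng = np.random.default_rng(seed)
        if config.pretrained is not None:
            self.encoder = load_pretrained_adapter(config.pretrained,
                                                   config.encoder_config())
        else:
            self.encoder = Encoder.init(rng, vocab, config.encoder_config())
        d = config.hidden_size
        self.subject_head = PointerHead.init(rng, d, 1)
        self.condition_maps = ConditionMaps.init(d)
        self.tha = TalkingHeadWeights.init(rng, d, config.tha_heads,
                                           talking=config.use_tha)
        self.relation_head = PointerHead.init(rng, d, len(schema))
        self._train_rng = np.random.default_rng(seed + 1)

    # -- parameters ----------------------------------------------------------

    def parameters(self) -> list[nn.Parameter]:
        return (self.encoder.parameters() + self.subject_head.parameters() +
                self.condition_maps.parameters() + self.tha.parameters() +
                self.relation_head.parameters())

    @property
    def vocab(self) -> Vocabulary:
        return self.encoder.vocab

    # -- forward pieces --------------------------------------------------------

    def encode(self, token_ids: np.ndarray, mask: np.ndarray | None = None,
               train: bool = False) -> EncodedSentence:
        return self.encoder.encode(token_ids, mask=mask, train=train,
                                   rng=self._train_rng if train else None)

    def forward_subjects(self, encoded: EncodedSentence) -> tuple[Tensor, Tensor]:
        """Per-token subject start/end probabilities (shape of the mask)."""
        start, end = pointer_probabilities(encoded.h, self.subject_head)
        # drop the trailing width-1 axis
        return (start.reshape(start.shape[:-1]), end.reshape(end.shape[:-1]))

    @staticmethod
    def subject_vector(encoded: EncodedSentence, span: SubjectSpan) -> Tensor:
        """Mean of the encoder features over the (half-open) subject span."""
        if encoded.h.ndim != 2:
            raise ValueError("subject_vector expects a single [n, d] sentence")
        n = encoded.h.shape[0]
        if span.end > n:
            raise ValueError(f"span [{span.start},{span.end}) outside sentence of {n}")
        pool = np.zeros((1, n))
        pool[0, span.start:span.end] = 1.0 / (span.end - span.start)
        return (Tensor(pool) @ encoded.h).reshape(encoded.h.shape[1])

    def _relation_pipeline(self, h: Tensor, v: Tensor,
                           mask: np.ndarray) -> tuple[Tensor, Tensor]:
        """Batched stage 2: h [M, n, d], v [M, d] -> start/end probs [M, n, R]."""
        if self.config.use_cln:
            cond = make_condition(v, self.condition_maps)
            hhat = conditional_layer_norm(h, cond, eps=self.config.cln_eps)
        else:
            from .layers import layer_norm_stats
            hhat = layer_norm_stats(h, self.config.cln_eps)
        n = h.shape[-2]
        H = hhat + self.encoder.position_table[np.arange(n)]  # position fusion
        if self.config.use_tha:
            O = talking_head_attention(H, self.tha, self.config.tha_heads, mask=mask)
        else:
            O = multi_head_attention(H, self.tha, self.config.tha_heads, mask=mask)
        feats = O + v.reshape(v.shape[0], 1, v.shape[1])
        return pointer_probabilities(feats, self.relation_head)

    def forward_relations(self, encoded: EncodedSentence,
                          subject: SubjectSpan) -> tuple[Tensor, Tensor]:
        """Object start/end probabilities [n, R] for one subject of one sentence."""
        if encoded.h.ndim != 2:
            raise ValueError("forward_relations expects a single [n, d] sentence")
        v = self.subject_vector(encoded, subject)
        n, d = encoded.h.shape
        start, end = self._relation_pipeline(
            encoded.h.reshape(1, n, d), v.reshape(1, d),
            encoded.mask.reshape(1, n))
        R = len(self.schema)
        return start.reshape(n, R), end.reshape(n, R)

    # -- decoding-facing probability interface ---------------------------------

    def tag_probabilities(self, tokens: Sequence[str]):
        """Eval-mode probability provider for the decoder (see decoding module)."""
        ids = self.vocab.encode(tokens)
        with no_grad():
            encoded = self.encode(ids)
            s_start, s_end = self.forward_subjects(encoded)

        model = self

        class _Probs:
            subject_start = s_start.data
            subject_end = s_end.data

            @staticmethod
            def objects(span: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
                with no_grad():
                    o_start, o_end = model.forward_relations(
                        encoded, SubjectSpan(*span))
                return o_start.data, o_end.data

        return _Probs()

    # -- checkpointing ----------------------------------------------------------

    _EXTRA = ("subject_head", "condition_maps", "tha", "relation_head")

    def _named_parameters(self) -> dict[str, nn.Parameter]:
        named: dict[str, nn.Parameter] = {}
        for i, p in enumerate(self.encoder.parameters()):
            named[f"encoder.{i}"] = p
        for group in self._EXTRA:
            for i, p in enumerate(getattr(self, group).parameters()):
                named[f"{group}.{i}"] = p
        return named

    def save(self, path: str | Path) -> None:
        """Versioned checkpoint: all weights + config + schema + vocabulary."""
        meta = {
            "format_version": 1,
            "config": {k: getattr(self.config, k) for k in self.config.__dataclass_fields__},
            "schema": list(self.schema.predicates),
            "vocab": self.vocab.chars,
        }
        arrays = {name: p.data for name, p in self._named_parameters().items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CascadeTagger":
        with np.load(path, allow_pickle=False) as ckpt:
            meta = json.loads(bytes(ckpt["__meta__"]).decode("utf-8"))
            if meta.get("format_version") != 1:
                raise ValueError(f"unsupported checkpoint version in {path}")
            cfg = dict(meta["config"])
            cfg["pretrained"] = None  # weights come from this checkpoint
            config = ModelConfig(**cfg)
            schema = RelationSchema(tuple(meta["schema"]))
            vocab = Vocabulary(meta["vocab"])
            model = cls(config, schema, vocab, seed=0)
            for name, p in model._named_parameters().items():
                p.data = np.array(ckpt[name])
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self._named_parameters().items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self._named_parameters().items():
            p.data = state[k].copy()


# ---------------------------------------------------------------------------
# objective


def bernoulli_log_likelihood(probs: Tensor, tags: np.ndarray,
                             mask: np.ndarray | None = None) -> Tensor:
    """sum over positions of tag*log(p) + (1-tag)*log(1-p), probabilities
    clipped to [eps, 1-eps]."""
    p = clip(probs, LOSS_EPS, 1.0 - LOSS_EPS)
    tags = np.asarray(tags, dtype=np.float64)
    ll = Tensor(tags) * log(p) + Tensor(1.0 - tags) * log(1.0 - p)
    if mask is not None:
        ll = ll * np.asarray(mask, dtype=np.float64)
    return ll.sum()


def loss_K(subj_probs: tuple, gold_subj: tuple,
           obj_probs: Sequence[tuple], gold_obj: Sequence[tuple]) -> Tensor:
    """-K for one sentence (or additively, a set of them).

    ``subj_probs``/``gold_subj``: (start, end) vectors over tokens.
    ``obj_probs``/``gold_obj``: per traversed subject, (start, end) [n, R]
    probability and tag matrices.
    """
    k = bernoulli_log_likelihood(_t(subj_probs[0]), gold_subj[0]) + \
        bernoulli_log_likelihood(_t(subj_probs[1]), gold_subj[1])
    for (ps, pe), (ts, te) in zip(obj_probs, gold_obj):
        k = k + bernoulli_log_likelihood(_t(ps), ts) + bernoulli_log_likelihood(_t(pe), te)
    return -k


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# gold tags


@dataclass
class GoldTags:
    """Binary start/end tag vectors for subjects and, per gold subject,
    start/end tag matrices for objects under every relation."""

    subj_start: np.ndarray              # [n]
    subj_end: np.ndarray                # [n]
    subjects: list[SubjectSpan]         # traversal order
    obj_start: list[np.ndarray]         # per subject: [n, R]
    obj_end: list[np.ndarray]


def build_gold_tags(sentence: AnnotatedSentence, schema: RelationSchema) -> GoldTags:
    """Teacher-forcing targets; every gold subject of the sentence is traversed."""
    n = len(sentence.tokens)
    R = len(schema)
    subj_start = np.zeros(n)
    subj_end = np.zeros(n)
    by_subject: dict[tuple[int, int], list] = {}
    for t in sentence.triplets:
        if t.subject_span is None or t.object_span is None:
            raise ValueError("training requires resolved spans")
        by_subject.setdefault(t.subject_span, []).append(t)
        subj_start[t.subject_span[0]] = 1.0
        subj_end[t.subject_span[1] - 1] = 1.0
    subjects, obj_start, obj_end = [], [], []
    for span, triplets in sorted(by_subject.items()):
        subjects.append(SubjectSpan(*span))
        os_, oe_ = np.zeros((n, R)), np.zeros((n, R))
        for t in triplets:
            r = schema.id_of(t.predicate)
            os_[t.object_span[0], r] = 1.0
            oe_[t.object_span[1] - 1, r] = 1.0
        obj_start.append(os_)
        obj_end.append(oe_)
    return GoldTags(subj_start, subj_end, subjects, obj_start, obj_end)
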