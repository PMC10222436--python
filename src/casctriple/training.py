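"""Training loop: seeded epoch shuffling, teacher forcing over every gold
subject, Adam with plateau learning-rate decay, gradient clipping, and
steady-state stopping on the objective.

The recorded per-epoch loss is -K divided by the number of Bernoulli terms
(tag positions) it sums over, i.e. a mean binary cross-entropy; this keeps
the learning rate meaningful across corpus and sentence sizes while leaving
the optimisation objective proportional to K.  Steady state is
operationalised as: no relative improvement above ``tol`` within the last
``patience`` epochs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._tensor import Tensor
from . import nn
from .corpus import AnnotatedSentence, RelationSchema
from .encoder import Vocabulary
from .model import (CascadeTagger, GoldTags, ModelConfig, build_gold_tags,
                    bernoulli_log_likelihood)


@dataclass(frozen=True)
class TrainConfig:
    """Desk-scale defaults; ``full_scale()`` restores the original profile
    (lr 1e-5, batch 8) appropriate for a pretrained 768-wide encoder."""

    batch_size: int = 8
    lr: float = 1e-3
    epochs: int = 100
    patience: int = 5
    tol: float = 1e-4
    lr_decay: float = 0.5
    lr_patience: int = 3
    clip_norm: float = 1.0
    seed: int = 0

    @classmethod
    def full_scale(cls, **overrides) -> "TrainConfig":
        base = dict(batch_size=8, lr=1e-5)
        base.update(overrides)
        return cls(**base)


def early_stop(history: Sequence[float], patience: int, tol: float) -> bool:
    """True iff the last ``patience`` epochs brought no relative improvement > tol."""
    if patience < 1:
        raise ValueError("patience must be >= 1")
    if len(history) <= patience:
        return False
    best_before = min(history[:-patience])
    recent_best = min(history[-patience:])
    return recent_best > best_before - tol * max(1e-12, abs(best_before))


@dataclass
class _Prepared:
    ids: np.ndarray
    gold: GoldTags


def _prepare(corpus: Sequence[AnnotatedSentence], schema: RelationSchema,
             vocab: Vocabulary) -> list[_Prepared]:
    prepared = []
    for sent in corpus:
        if not sent.tokens:
            continue
        prepared.append(_Prepared(vocab.encode(sent.tokens),
                                  build_gold_tags(sent, schema)))
    if not prepared:
        raise ValueError("training corpus is empty")
    return prepared


def _batch_loss(model: CascadeTagger, batch: list[_Prepared],
                train: bool = True) -> tuple[Tensor, int, int]:
    """(-K over the batch, number of Bernoulli terms, relation invocations)."""
    n = max(len(p.ids) for p in batch)
    B = len(batch)
    ids = np.zeros((B, n), dtype=np.int64)
    mask = np.zeros((B, n), dtype=bool)
    subj_start = np.zeros((B, n))
    subj_end = np.zeros((B, n))
    for i, p in enumerate(batch):
        L = len(p.ids)
        ids[i, :L] = p.ids
        mask[i, :L] = True
        subj_start[i, :L] = p.gold.subj_start
        subj_end[i, :L] = p.gold.subj_end

    encoded = model.encode(ids, mask=mask, train=train)
    s_start, s_end = model.forward_subjects(encoded)
    fmask = mask.astype(np.float64)
    k = bernoulli_log_likelihood(s_start, subj_start, fmask) + \
        bernoulli_log_likelihood(s_end, subj_end, fmask)
    n_terms = 2 * int(mask.sum())

    # teacher forcing: traverse every gold subject of every sentence
    sent_idx, pools, ostart, oend = [], [], [], []
    R = len(model.schema)
    for i, p in enumerate(batch):
        L = len(p.ids)
        for span, os_, oe_ in zip(p.gold.subjects, p.gold.obj_start, p.gold.obj_end):
            sent_idx.append(i)
            pool = np.zeros((1, n))
            pool[0, span.start:span.end] = 1.0 / (span.end - span.start)
            pools.append(pool)
            pad_s = np.zeros((n, R))
            pad_e = np.zeros((n, R))
            pad_s[:L] = os_
            pad_e[:L] = oe_
            ostart.append(pad_s)
            oend.append(pad_e)
    m = len(sent_idx)
    if m:
        sidx = np.array(sent_idx)
        h_g = encoded.h[sidx]                               # [M, n, d]
        v = (Tensor(np.stack(pools)) @ h_g).reshape(m, model.config.hidden_size)
        o_start_p, o_end_p = model._relation_pipeline(h_g, v, mask[sidx])
        rel_mask = np.repeat(fmask[sidx][:, :, None], R, axis=2)
        k = k + bernoulli_log_likelihood(o_start_p, np.stack(ostart), rel_mask) + \
            bernoulli_log_likelihood(o_end_p, np.stack(oend), rel_mask)
        n_terms += 2 * R * int(mask[sidx].sum())
    return -k, n_terms, m


def train(corpus: Sequence[AnnotatedSentence], schema: RelationSchema,
          config: TrainConfig | None = None,
          model_config: ModelConfig | None = None,
          vocab: Vocabulary | None = None) -> tuple[CascadeTagger, dict]:
    """Fit a CascadeTagger; returns the best-loss model and the run history.

    History keys: ``loss`` (per-epoch mean BCE), ``lr``, ``grad_norm``,
    ``relation_invocations``, ``stopped_epoch``.
    """
    config = config or TrainConfig()
    model_config = model_config or ModelConfig()
    if vocab is None:
        vocab = Vocabulary.from_corpus(corpus)
    model = CascadeTagger(model_config, schema, vocab, seed=config.seed)
    prepared = _prepare(corpus, schema, vocab)
    params = model.parameters()
    opt = nn.Adam(params, lr=config.lr)
    rng = np.random.default_rng(config.seed)

    history: dict = {"loss": [], "lr": [], "grad_norm": [],
                     "relation_invocations": []}
    best_loss = np.inf
    best_state = model.state_copy()
    since_lr_drop = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(prepared))
        total_nll, total_terms, total_rel = 0.0, 0, 0
        gnorms = []
        for lo in range(0, len(prepared), config.batch_size):
            batch = [prepared[i] for i in order[lo:lo + config.batch_size]]
            nll, n_terms, n_rel = _batch_loss(model, batch, train=True)
            loss = nll * (1.0 / n_terms)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}")
            nn.zero_grads(params)
            loss.backward()
            gnorms.append(nn.clip_global_norm(params, config.clip_norm))
            opt.step()
            total_nll += float(nll.data)
            total_terms += n_terms
            total_rel += n_rel
        epoch_loss = total_nll / total_terms
        history["loss"].append(epoch_loss)
        history["lr"].append(opt.lr)
        history["grad_norm"].append(float(np.mean(gnorms)))
        history["relation_invocations"].append(total_rel)

        improved = epoch_loss < best_loss - config.tol * max(1e-12, abs(best_loss))
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_state = model.state_copy()
        if improved:
            since_lr_drop = 0
        else:
            since_lr_drop += 1
            if since_lr_drop >= config.lr_patience:
                opt.lr *= config.lr_decay
                since_lr_drop = 0
        if early_stop(history["loss"], config.patience, config.tol):
            break
    history["stopped_epoch"] = len(history["loss"])
    model.load_state(best_state)
    return model, history
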