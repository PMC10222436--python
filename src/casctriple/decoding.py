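"""Turn tag probabilities into spans and triplets.

Span decoding follows the nearest start-end match rule: scanning start
positions left to right, each start is paired with the nearest end position
at or after it, considering only end tokens that precede the next start
(next-start fencing).  A start with no valid end is dropped rather than
extended, favouring entity integrity (precision) over recall.  End tags mark
the inclusive final token, so a start at i matched to an end at j yields the
half-open span [i, j+1).

Thresholding is strict (tag = 1 iff p > tau), so an untrained model whose
sigmoid outputs sit exactly at 0.5 emits nothing at the default tau = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .corpus import AnnotatedSentence, RelationSchema, Triplet


def threshold_tags(probs: np.ndarray, tau: float) -> np.ndarray:
    """Binary tags: 1 where probability strictly exceeds tau."""
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie strictly between 0 and 1")
    return (np.asarray(probs) > tau).astype(np.int8)


def match_spans(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int]]:
    """Pair start tags with the nearest end tag under next-start fencing.

    ``starts``/``ends`` are binary vectors; returns sorted half-open spans.
    """
    starts = np.asarray(starts).ravel()
    ends = np.asarray(ends).ravel()
    start_pos = np.flatnonzero(starts)
    end_pos = np.flatnonzero(ends)
    spans: list[tuple[int, int]] = []
    for idx, s in enumerate(start_pos):
        fence = start_pos[idx + 1] if idx + 1 < len(start_pos) else len(starts)
        candidates = end_pos[(end_pos >= s) & (end_pos < fence)]
        if candidates.size:
            spans.append((int(s), int(candidates[0]) + 1))
    return spans


class TagProbabilityProvider(Protocol):
    """What the decoder needs from a model (or a rigged fixture)."""

    schema: RelationSchema

    def tag_probabilities(self, tokens: Sequence[str]): ...  # pragma: no cover


@dataclass
class DecodedTriplets:
    triplets: tuple[Triplet, ...]
    # per emitted triplet: (subject start prob, subject end prob,
    #                       object start prob, object end prob)
    provenance: tuple[tuple[float, float, float, float], ...] = ()


def decode_sentence(model: TagProbabilityProvider,
                    sentence: AnnotatedSentence | str,
                    tau_subj: float = 0.5, tau_rel: float = 0.5) -> DecodedTriplets:
    """Full cascade decoding of one sentence.

    Subjects are decoded from the stage-1 probabilities; for each decoded
    subject the stage-2 probabilities are computed and object spans matched
    independently per relation.  Duplicate (subject_span, predicate,
    object_span) triplets are removed.
    """
    if isinstance(sentence, str):
        text = sentence
        tokens = tuple(text)
    else:
        text, tokens = sentence.text, sentence.tokens
        text = text[:len(tokens)]
    if not tokens:
        return DecodedTriplets(())
    probs = model.tag_probabilities(tokens)
    subj_spans = match_spans(threshold_tags(probs.subject_start, tau_subj),
                             threshold_tags(probs.subject_end, tau_subj))
    schema = model.schema
    seen: set[tuple] = set()
    out: list[Triplet] = []
    prov: list[tuple[float, float, float, float]] = []
    for s_start, s_end in subj_spans:
        o_start_p, o_end_p = probs.objects((s_start, s_end))
        o_start = threshold_tags(o_start_p, tau_rel)
        o_end = threshold_tags(o_end_p, tau_rel)
        for r, predicate in enumerate(schema.predicates):
            for ob_start, ob_end in match_spans(o_start[:, r], o_end[:, r]):
                key = ((s_start, s_end), predicate, (ob_start, ob_end))
                if key in seen:
                    continue
                seen.add(key)
                out.append(Triplet(
                    subject=text[s_start:s_end], predicate=predicate,
                    object=text[ob_start:ob_end],
                    subject_span=(s_start, s_end), object_span=(ob_start, ob_end)))
                prov.append((float(probs.subject_start[s_start]),
                             float(probs.subject_end[s_end - 1]),
                             float(o_start_p[ob_start, r]),
                             float(o_end_p[ob_end - 1, r])))
    return DecodedTriplets(tuple(out), tuple(prov))


def predict_corpus(model: TagProbabilityProvider,
                   sentences: Sequence[AnnotatedSentence],
                   tau_subj: float = 0.5,
                   tau_rel: float = 0.5) -> list[AnnotatedSentence]:
    """Decode every sentence, returning copies carrying predicted triplets."""
    out = []
    for sent in sentences:
        decoded = decode_sentence(model, sent, tau_subj, tau_rel)
        out.append(AnnotatedSentence(text=sent.text, tokens=sent.tokens,
                                     triplets=decoded.triplets))
    return out
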