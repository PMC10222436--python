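"""Corpus I/O: the JSONL "spo_list" dialect, relation schemas, and
character-level tokenization with span bookkeeping.

Records look like::

    {"text": "...", "spo_list": [{"subject": "...", "predicate": "...", "object": "..."}]}

one JSON object per line, UTF-8.  Surface forms are localized in the text by
first occurrence when the file carries no offsets (the public dialect does
not); every resolved span satisfies ``text[start:end] == surface``.

Spans are 0-based half-open character/token intervals throughout the
package; the tagging layers mark a span's start at ``start`` and its end at
``end - 1`` (inclusive end token), converting at that boundary only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

logger = logging.getLogger(__name__)


class CorpusError(ValueError):
    """Malformed corpus input (bad JSON, unknown predicate, unresolvable span)."""


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelationSchema:
    """Ordered inventory of predicate names; defines the object tagger width R."""

    predicates: tuple[str, ...]

    def __post_init__(self):
        if len(self.predicates) < 1:
            raise CorpusError("schema needs at least one predicate")
        if len(set(self.predicates)) != len(self.predicates):
            raise CorpusError("predicate names must be unique")
        object.__setattr__(self, "predicates", tuple(self.predicates))

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.predicates)}

    def __len__(self) -> int:
        return len(self.predicates)

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def id_of(self, name: str) -> int:
        try:
            return self.index[name]
        except KeyError:
            raise CorpusError(f"unknown predicate {name!r}; schema has {self.predicates}")

    @classmethod
    def load(cls, path: str | Path) -> "RelationSchema":
        """Read a schema file: a YAML or JSON array of predicate names."""
        text = Path(path).read_text(encoding="utf-8")
        names = yaml.safe_load(text)
        if not isinstance(names, list) or not all(isinstance(n, str) for n in names):
            raise CorpusError(f"schema file {path} must be a flat list of names")
        return cls(tuple(names))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(list(self.predicates), allow_unicode=True), encoding="utf-8"
        )


@dataclass(frozen=True)
class Triplet:
    """(subject, predicate, object) with optional half-open token spans."""

    subject: str
    predicate: str
    object: str
    subject_span: tuple[int, int] | None = None
    object_span: tuple[int, int] | None = None

    def surfaces(self) -> tuple[str, str, str]:
        return (self.subject, self.predicate, self.object)


@dataclass(frozen=True)
class AnnotatedSentence:
    text: str
    tokens: tuple[str, ...]
    triplets: tuple[Triplet, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "triplets", tuple(self.triplets))


# ---------------------------------------------------------------------------


def tokenize(text: str, max_length: int = 128) -> tuple[str, ...]:
    """Character-level tokenization, hard-truncated at ``max_length``."""
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    return tuple(text[:max_length])


def resolve_span(text: str, surface: str) -> tuple[int, int]:
    """First occurrence of ``surface`` in ``text`` as a half-open interval."""
    start = text.find(surface)
    if start < 0:
        raise CorpusError(f"surface {surface!r} not found in text {text!r}")
    return (start, start + len(surface))


def annotate(text: str, spo_list: Sequence[dict], schema: RelationSchema,
             max_length: int = 128) -> AnnotatedSentence:
    """Build an AnnotatedSentence, resolving spans by first occurrence.

    Triplets whose span crosses the truncation boundary are dropped with a
    warning; unknown predicates and unresolvable surfaces raise CorpusError.
    """
    tokens = tokenize(text, max_length)
    n = len(tokens)
    triplets: list[Triplet] = []
    dropped = 0
    for spo in spo_list:
        predicate = spo["predicate"]
        if predicate not in schema:
            raise CorpusError(
                f"unknown predicate {predicate!r} in record {text!r}")
        subj, obj = spo["subject"], spo["object"]
        s_span = resolve_span(text, subj)
        o_span = resolve_span(text, obj)
        if s_span[1] > n or o_span[1] > n:
            dropped += 1
            continue
        triplets.append(Triplet(subj, predicate, obj, s_span, o_span))
    if dropped:
        logger.warning("dropped %d triplet(s) beyond max_length=%d in %r",
                       dropped, max_length, text[:30])
    return AnnotatedSentence(text=text, tokens=tokens, triplets=tuple(triplets))


def read_jsonl(path: str | Path, schema: RelationSchema,
               max_length: int = 128) -> list[AnnotatedSentence]:
    """Read a JSONL spo-list corpus, validating predicates against the schema."""
    sentences: list[AnnotatedSentence] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            if "text" not in record or "spo_list" not in record:
                raise CorpusError(f"{path}:{lineno}: record needs 'text' and 'spo_list'")
            try:
                sentences.append(
                    annotate(record["text"], record["spo_list"], schema, max_length))
            except CorpusError as exc:
                raise CorpusError(f"{path}:{lineno}: {exc}") from exc
    return sentences


def to_record(sentence: AnnotatedSentence) -> dict:
    return {
        "text": sentence.text,
        "spo_list": [
            {"subject": t.subject, "predicate": t.predicate, "object": t.object}
            for t in sentence.triplets
        ],
    }


def write_jsonl(sentences: Iterable[AnnotatedSentence], path: str | Path) -> None:
    """Write sentences in the spo-list dialect (round-trips with read_jsonl)."""
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            fh.write(json.dumps(to_record(sent), ensure_ascii=False) + "\n")


def retokenize(sentence: AnnotatedSentence, max_length: int) -> AnnotatedSentence:
    """Re-apply the truncation policy to an in-memory sentence."""
    kept = [t for t in sentence.triplets
            if t.subject_span is None or
            (t.subject_span[1] <= max_length and t.object_span[1] <= max_length)]
    return replace(sentence, tokens=tokenize(sentence.text, max_length),
                   triplets=tuple(kept))
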