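"""Synthetic spo-list corpora with controllable overlap-class composition.

The generator emulates the character-level structure of Chinese
information-extraction corpora: multi-character entity mentions embedded in
distractor text, with a fixed relation schema and sentences built to realise
a requested mix of Normal / EPO / SEO overlap classes exactly.

Learnability is by construction.  Entities come from four lexical classes
with pairwise-disjoint character alphabets (two subject classes A and B, two
object classes X and Y; distractor characters use a fifth alphabet), so a
token's class is readable from the character itself.  The relation between a
subject of class s and an object of class o is the deterministic rule
``r = (2*s + o) mod R``; the designated EPO class pair (B, Y) always carries
that relation and its successor mod R, realising entity-pair overlap.  A
subject relates to exactly the objects appearing between it and the next
subject (adjacency pairing), so the gold triplet set is a deterministic
function of the text and the Bayes-optimal exact-match F1 is 1.0.

Class templates:

* Normal: one subject-object pair, or two pairs with four distinct entities.
* EPO: one (B, Y) pair -> two triplets sharing both entities.
* SEO: one class-A subject with one X and one Y object -> two triplets
  sharing the subject only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import AnnotatedSentence, RelationSchema, Triplet

# Disjoint alphabets in the CJK unified-ideograph range, exercising the
# UTF-8 path that Chinese corpora require.
_ALPHABET_SIZE = 24
_CLASS_BASE = {0: 0x4E00, 1: 0x4E40, 2: 0x4E80, 3: 0x4EC0}  # A, B, X, Y
_DISTRACTOR_BASE = 0x5000
SUBJ_A, SUBJ_B, OBJ_X, OBJ_Y = 0, 1, 2, 3


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    n_sentences: int = 100
    class_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)  # Normal, EPO, SEO
    n_relations: int = 4
    entity_lexicon_size: int = 40          # per lexical class
    entity_len_range: tuple[int, int] = (2, 4)
    distractor_rate: float = 0.4
    two_pair_normal_fraction: float = 0.5  # Normal sentences with two disjoint pairs
    seed: int = 0

    def __post_init__(self):
        if self.n_sentences < 1:
            raise GeneratorConfigError("n_sentences must be positive")
        if any(p < 0 for p in self.class_mix) or abs(sum(self.class_mix) - 1) > 1e-9:
            raise GeneratorConfigError("class_mix must be non-negative and sum to 1")
        if self.n_relations < 1:
            raise GeneratorConfigError("n_relations must be positive")
        if self.class_mix[1] > 0 and self.n_relations < 2:
            raise GeneratorConfigError(
                "EPO sentences need at least 2 relations (same pair, two predicates)")
        lo, hi = self.entity_len_range
        if not (1 <= lo <= hi):
            raise GeneratorConfigError("invalid entity_len_range")
        if not (0.0 <= self.distractor_rate <= 1.0):
            raise GeneratorConfigError("distractor_rate must lie in [0, 1]")
        if self.entity_lexicon_size < 4:
            raise GeneratorConfigError("lexicon too small to avoid collisions")


def default_schema(n_relations: int = 4) -> RelationSchema:
    return RelationSchema(tuple(f"r{i}" for i in range(n_relations)))


def relation_rule(subj_class: int, obj_class: int, n_relations: int) -> list[int]:
    """Deterministic relation assignment from lexical classes."""
    base = (2 * (subj_class - SUBJ_A) + (obj_class - OBJ_X)) % n_relations
    if (subj_class, obj_class) == (SUBJ_B, OBJ_Y):
        return [base, (base + 1) % n_relations]
    return [base]


def _build_lexicon(rng: np.random.Generator, config: GeneratorConfig) -> dict[int, list[str]]:
    lex: dict[int, list[str]] = {}
    lo, hi = config.entity_len_range
    for cls, base in _CLASS_BASE.items():
        alphabet = [chr(base + i) for i in range(_ALPHABET_SIZE)]
        words: set[str] = set()
        guard = 0
        while len(words) < config.entity_lexicon_size:
            length = int(rng.integers(lo, hi + 1))
            word = "".join(rng.choice(alphabet, size=length))
            words.add(word)
            guard += 1
            if guard > 100 * config.entity_lexicon_size:
                raise GeneratorConfigError(
                    "cannot build a collision-free lexicon; enlarge entity_len_range")
        lex[cls] = sorted(words)
    return lex


def _class_counts(config: GeneratorConfig) -> dict[str, int]:
    """Largest-remainder apportionment so requested proportions hold exactly."""
    from .evaluation import CLASSES
    raw = [p * config.n_sentences for p in config.class_mix]
    counts = [int(np.floor(x)) for x in raw]
    remainder = config.n_sentences - sum(counts)
    order = np.argsort([c - x for c, x in zip(counts, raw)])  # largest remainders first
    for i in range(remainder):
        counts[order[i]] += 1
    return dict(zip(CLASSES, counts))


def _distractor_run(rng: np.random.Generator, rate: float, leading: bool) -> str:
    alphabet = [chr(_DISTRACTOR_BASE + i) for i in range(2 * _ALPHABET_SIZE)]
    max_extra = int(round(5 * rate))
    length = int(rng.integers(0 if leading else 1, max_extra + 2))
    return "".join(rng.choice(alphabet, size=length)) if length else ""


def _sample_entities(rng, lexicon, classes: list[int]) -> list[str]:
    """Distinct surfaces, one per requested class."""
    chosen: list[str] = []
    for cls in classes:
        while True:
            word = lexicon[cls][int(rng.integers(len(lexicon[cls])))]
            if word not in chosen:
                chosen.append(word)
                break
    return chosen


def _compose(rng, config: GeneratorConfig, groups: list[tuple[str, list[str]]],
             schema: RelationSchema, classes_of: dict[str, int]) -> AnnotatedSentence | None:
    """Lay out subject groups left to right and derive the gold triplets.

    Returns None when a surface's first occurrence is not its placed span
    (caller resamples), so spo-list round-trips resolve spans exactly.
    """
    text = _distractor_run(rng, config.distractor_rate, leading=True)
    spans: dict[str, tuple[int, int]] = {}
    triplets: list[Triplet] = []
    for subj, objects in groups:
        start = len(text)
        text += subj
        spans[subj] = (start, len(text))
        for obj in objects:
            text += _distractor_run(rng, config.distractor_rate, leading=False)
            start = len(text)
            text += obj
            spans[obj] = (start, len(text))
        text += _distractor_run(rng, config.distractor_rate, leading=False)
    for subj, objects in groups:
        for obj in objects:
            for r in relation_rule(classes_of[subj], classes_of[obj],
                                   len(schema)):
                triplets.append(Triplet(subj, schema.predicates[r], obj,
                                        spans[subj], spans[obj]))
    for surface, (start, end) in spans.items():
        if text.find(surface) != start:
            return None
    return AnnotatedSentence(text=text, tokens=tuple(text), triplets=tuple(triplets))


def _make_sentence(rng, config: GeneratorConfig, cls: str,
                   schema: RelationSchema, lexicon) -> AnnotatedSentence:
    from .evaluation import EPO, NORMAL, SEO
    for _ in range(200):
        if cls == NORMAL:
            single_combos = [(SUBJ_A, OBJ_X), (SUBJ_A, OBJ_Y), (SUBJ_B, OBJ_X)]
            if rng.random() < config.two_pair_normal_fraction:
                combo1 = single_combos[int(rng.integers(3))]
                combo2 = single_combos[int(rng.integers(3))]
                ents = _sample_entities(rng, lexicon,
                                        [combo1[0], combo1[1], combo2[0], combo2[1]])
                groups = [(ents[0], [ents[1]]), (ents[2], [ents[3]])]
                classes_of = dict(zip(ents, [combo1[0], combo1[1], combo2[0], combo2[1]]))
            else:
                combo = single_combos[int(rng.integers(3))]
                ents = _sample_entities(rng, lexicon, list(combo))
                groups = [(ents[0], [ents[1]])]
                classes_of = dict(zip(ents, combo))
        elif cls == EPO:
            ents = _sample_entities(rng, lexicon, [SUBJ_B, OBJ_Y])
            groups = [(ents[0], [ents[1]])]
            classes_of = dict(zip(ents, [SUBJ_B, OBJ_Y]))
        elif cls == SEO:
            obj_classes = [OBJ_X, OBJ_Y] if rng.random() < 0.5 else [OBJ_Y, OBJ_X]
            ents = _sample_entities(rng, lexicon, [SUBJ_A] + obj_classes)
            groups = [(ents[0], [ents[1], ents[2]])]
            classes_of = dict(zip(ents, [SUBJ_A] + obj_classes))
        else:
            raise GeneratorConfigError(f"unknown class {cls!r}")
        sent = _compose(rng, config, groups, schema, classes_of)
        if sent is None:
            continue
        # two-pair Normal sentences must not accidentally share an entity
        from .evaluation import overlap_class
        if overlap_class(sent) == cls:
            return sent
    raise GeneratorConfigError(f"could not realise class {cls} (lexicon too small?)")


def generate_corpus(config: GeneratorConfig,
                    schema: RelationSchema | None = None) -> list[AnnotatedSentence]:
    """Generate a schema-valid corpus realising the class mix exactly.

    Deterministic under ``config.seed``: the same config yields a
    byte-identical corpus.
    """
    schema = schema or default_schema(config.n_relations)
    if len(schema) != config.n_relations:
        raise GeneratorConfigError("schema size must equal n_relations")
    rng = np.random.default_rng(config.seed)
    lexicon = _build_lexicon(rng, config)
    counts = _class_counts(config)
    labels = [c for c, k in counts.items() for _ in range(k)]
    rng.shuffle(labels)
    return [_make_sentence(rng, config, cls, schema, lexicon) for cls in labels]


# ---------------------------------------------------------------------------
# worked single-sentence fixture


@dataclass
class RiggedTagger:
    """Hand-set probability tensors exposed through the decoder's interface."""

    schema: RelationSchema
    subject_start: np.ndarray
    subject_end: np.ndarray
    object_probs: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]
    background: float = 0.1

    def tag_probabilities(self, tokens):
        rig = self

        class _Probs:
            subject_start = rig.subject_start
            subject_end = rig.subject_end

            @staticmethod
            def objects(span):
                if span in rig.object_probs:
                    return rig.object_probs[span]
                n, R = len(rig.subject_start), len(rig.schema)
                return (np.full((n, R), rig.background),
                        np.full((n, R), rig.background))

        return _Probs()


def generate_figure1_fixture(confidence: float = 0.9
                             ) -> tuple[AnnotatedSentence, RiggedTagger]:
    """The worked pancreatic-cancer example as a decodable fixture.

    A three-entity sentence whose subject tagger fires on all three entity
    spans; conditioned on the subject "pancreatic cancer", the object tagger
    fires for the relation "imageological examination" on "ultrasonic
    examination" and for "clinical manifestation" on "pancreatic mass", while
    the relation "age" never fires and the other two subjects yield nothing.
    Decoding at tau below ``confidence`` must therefore produce exactly the
    two triplets; any tau above it produces none.
    """
    schema = RelationSchema(("imageological examination", "age",
                             "clinical manifestation"))
    subj = "pancreatic cancer"
    obj1 = "ultrasonic examination"
    obj2 = "pancreatic mass"
    text = f"{subj}: {obj1}; {obj2}."
    spans = {name: (text.find(name), text.find(name) + len(name))
             for name in (subj, obj1, obj2)}
    gold = (
        Triplet(subj, "imageological examination", obj1, spans[subj], spans[obj1]),
        Triplet(subj, "clinical manifestation", obj2, spans[subj], spans[obj2]),
    )
    sentence = AnnotatedSentence(text=text, tokens=tuple(text), triplets=gold)

    n, R = len(text), len(schema)
    lo = 1.0 - confidence
    s_start = np.full(n, lo)
    s_end = np.full(n, lo)
    for start, end in spans.values():
        s_start[start] = confidence
        s_end[end - 1] = confidence
    o_start = np.full((n, R), lo)
    o_end = np.full((n, R), lo)
    o_start[spans[obj1][0], 0] = confidence
    o_end[spans[obj1][1] - 1, 0] = confidence
    o_start[spans[obj2][0], 2] = confidence
    o_end[spans[obj2][1] - 1, 2] = confidence
    rig = RiggedTagger(schema, s_start, s_end,
                       {spans[subj]: (o_start, o_end)}, background=lo)
    return sentence, rig
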