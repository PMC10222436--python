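"""Model / Results interface.

``TripletExtractor`` is built from a corpus and a relation schema;
``fit()`` trains the cascade tagger and returns ``TripletExtractorResults``
carrying the fitted parameters, the loss history and evaluation utilities::

    schema = default_schema(4)
    corpus = generate_corpus(GeneratorConfig(n_sentences=200, seed=1), schema)
    model = TripletExtractor(corpus, schema)
    res = model.fit(TrainConfig(epochs=30, seed=1))
    print(res.summary())
    report = res.evaluate(heldout)
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .corpus import AnnotatedSentence, RelationSchema
from .decoding import DecodedTriplets, decode_sentence, predict_corpus
from .evaluation import EvalReport, evaluate
from .model import CascadeTagger, ModelConfig
from .training import TrainConfig, train


class TripletExtractor:
    """Joint entity-relation triplet extraction model bound to a corpus."""

    def __init__(self, corpus: Sequence[AnnotatedSentence],
                 schema: RelationSchema,
                 config: ModelConfig | None = None):
        if not corpus:
            raise ValueError("corpus must be non-empty")
        self.corpus = list(corpus)
        self.schema = schema
        self.config = config or ModelConfig()

    @classmethod
    def from_jsonl(cls, corpus_path: str | Path, schema_path: str | Path,
                   config: ModelConfig | None = None) -> "TripletExtractor":
        from .corpus import read_jsonl
        schema = RelationSchema.load(schema_path)
        config = config or ModelConfig()
        return cls(read_jsonl(corpus_path, schema, config.max_length),
                   schema, config)

    def fit(self, train_config: TrainConfig | None = None) -> "TripletExtractorResults":
        tagger, history = train(self.corpus, self.schema,
                                config=train_config or TrainConfig(),
                                model_config=self.config)
        return TripletExtractorResults(self, tagger, history,
                                       train_config or TrainConfig())


class TripletExtractorResults:
    """Fitted extractor: parameters, training diagnostics, decode/evaluate."""

    def __init__(self, model: TripletExtractor, tagger: CascadeTagger,
                 history: dict, train_config: TrainConfig):
        self.model = model
        self.tagger = tagger
        self.history = history
        self.train_config = train_config

    # -- inference -------------------------------------------------------------

    def extract(self, text: str, tau_subj: float = 0.5,
                tau_rel: float = 0.5) -> DecodedTriplets:
        """Decode triplets from raw text."""
        return decode_sentence(self.tagger, text, tau_subj, tau_rel)

    def predict(self, sentences: Sequence[AnnotatedSentence],
                tau_subj: float = 0.5, tau_rel: float = 0.5) -> list[AnnotatedSentence]:
        return predict_corpus(self.tagger, sentences, tau_subj, tau_rel)

    def evaluate(self, gold: Sequence[AnnotatedSentence], by_class: bool = True,
                 tau_subj: float = 0.5, tau_rel: float = 0.5) -> EvalReport:
        """Decode ``gold`` sentences and score exact-match P/R/F1 against them."""
        pred = self.predict(gold, tau_subj, tau_rel)
        return evaluate(pred, gold, by_class=by_class)

    # -- persistence -----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        self.tagger.save(path)

    # -- reporting -------------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.tagger.parameters()))

    def summary(self) -> str:
        cfg = self.tagger.config
        loss = self.history["loss"]
        lines = [
            "Cascade binary-tagging triplet extractor",
            "=" * 48,
            f"relations (R):        {len(self.model.schema)}",
            f"hidden size:          {cfg.hidden_size}",
            f"encoder blocks/heads: {cfg.n_blocks} / {cfg.n_encoder_heads}",
            f"talking heads:        {cfg.tha_heads}"
            + ("" if cfg.use_tha else "  (disabled: plain multi-head)"),
            f"conditional LN:       {'on' if cfg.use_cln else 'off'}",
            f"parameters:           {self.n_parameters:,}",
            f"training sentences:   {len(self.model.corpus)}",
            f"epochs run:           {self.history['stopped_epoch']}"
            f" (max {self.train_config.epochs})",
            f"initial / final loss: {loss[0]:.4f} / {loss[-1]:.4f}"
            f"  (mean Bernoulli NLL per tag)",
            f"final learning rate:  {self.history['lr'][-1]:.2e}",
        ]
        return "\n".join(lines)
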