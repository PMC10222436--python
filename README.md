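# casctriple

Joint extraction of entity–relation triplets from sentences by **cascade
binary tagging**, for text where triplets overlap — the same entity pair
carrying two relations (EPO), or one entity shared across triplets (SEO) —
as is common in clinical and biomedical narratives ("pancreatic cancer –
imageological examination – ultrasonic examination" and "pancreatic cancer –
clinical manifestation – pancreatic mass" share a subject).

## Model

Given a character-tokenized sentence with encoder features
*h* ∈ ℝ^{n×d} (token + segment + position embeddings through a transformer
stack), extraction runs in two cascaded stages:

1. **Subject tagging.** Per-token sigmoid pointer classifiers
   *s*^start = σ(W_s^start h + b), *s*^end likewise; tags fire above a
   threshold τ and spans form by nearest start–end matching.
2. **Relation–object tagging**, once per subject with span representation
   *v* (mean of *h* over the span):

   *h* → CLN(*h*; γ(*v*), β(*v*)) → + *E_P* → talking-head attention → *O*,
   then per relation *r*: *r*^start = σ(W_r^start (*O* + *v*) + b), *r*^end
   likewise — an n × R probability matrix pair whose matched spans become
   the objects of (subject, r, object) triplets.

Here CLN is **conditional layer normalization** — layer norm whose scale and
shift are affine functions of the subject vector — and talking-head
attention mixes attention logits (λ_W, pre-softmax) and attention weights
(λ_L, post-softmax) across heads; with identity λ it reduces exactly to
plain multi-head attention. Training maximises the summed Bernoulli
log-likelihood *K* of all gold start/end tags (teacher-forced over every
gold subject) with Adam, plateau learning-rate decay and steady-state
stopping. The numerical core is a small numpy reverse-mode autodiff engine,
so the package has no deep-learning framework dependency.

Everything is evaluated by exact-match precision / recall / F1 with
per-overlap-class (Normal / EPO / SEO) breakdowns, and a synthetic corpus
generator produces spo-list JSONL corpora with an exactly controlled overlap
mix and Bayes-optimal F1 of 1.0 (see `docs/methods.md`).

## Worked example

```python
from casctriple import (GeneratorConfig, ModelConfig, TrainConfig,
                        TripletExtractor, default_schema, generate_corpus)

schema = default_schema(4)
corpus = generate_corpus(GeneratorConfig(n_sentences=1000, seed=11), schema)
model = TripletExtractor(corpus[:800], schema, ModelConfig(max_length=48))
res = model.fit(TrainConfig(epochs=40, seed=1))
print(res.summary())
print(res.evaluate(corpus[800:]))
```

prints (about two minutes on one CPU core):

```
Cascade binary-tagging triplet extractor
================================================
relations (R):        4
hidden size:          64
encoder blocks/heads: 2 / 4
talking heads:        8
conditional LN:       on
parameters:           137,418
training sentences:   800
epochs run:           40 (max 40)
initial / final loss: 0.1164 / 0.0000  (mean Bernoulli NLL per tag)
final learning rate:  5.00e-04
class       TP    FP    FN    prec     rec      F1
overall    327    13    22   0.962   0.937   0.949
EPO         90     0     0   1.000   1.000   1.000
Normal     126    13    21   0.906   0.857   0.881
SEO        111     0     1   1.000   0.991   0.996
```

i.e. the trained tagger recovers 94–100% of held-out triplets exactly, with
entity-pair-overlap and single-entity-overlap sentences — the hard cases the
cascade design targets — essentially solved; residual errors concentrate in
two-pair Normal sentences where stage 2 must pair each subject with only its
own objects.

The same study is available from the shell:

```bash
casctriple simulate --n-sentences 1000 --seed 11 --out corpus.jsonl --schema schema.yaml
casctriple train --train corpus.jsonl --schema schema.yaml --seed 1 --out model.npz
casctriple predict --model model.npz --input corpus.jsonl --output pred.jsonl
casctriple evaluate --gold corpus.jsonl --pred pred.jsonl --schema schema.yaml
casctriple ablate --train corpus.jsonl --dev corpus.jsonl --schema schema.yaml --out ablation.json
casctriple head-sweep --train corpus.jsonl --dev corpus.jsonl --schema schema.yaml --heads 1,2,4,8 --out sweep.csv
```

Every command writes a `*.manifest.json` sufficient to reproduce the run.

## Repository layout

- `src/casctriple/` — `corpus` (spo-list JSONL + schema I/O), `_tensor`/`nn`
  (autodiff core, Adam), `encoder`, `layers` (CLN, MHA/THA, pointer heads),
  `model` (cascade + objective), `decoding`, `training`, `evaluation`,
  `synthetic` (corpus generator + worked fixture), `experiments`
  (ablations, head sweep), `protocols` (canonical study sizes), `api`
  (Model/Results facade), `cli`.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — modelling assumptions, numerical choices, generator
  design, limitations.
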