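# Methods

## Problem and model

`casctriple` extracts relational triplets (subject *s*, predicate *r*,
object *o*) from single sentences, including *overlapping* triplets, by
cascade binary tagging. The model has two stages sharing one encoder:

**Encoder.** Characters are the tokens (no word segmentation; Chinese
clinical text is the motivating domain and character inputs avoid
segmentation-error coupling). Each token embeds as the sum of a token, a
segment and a learned position embedding, `x_t = E_T + E_S + E_P(t)`, and a
stack of post-norm transformer blocks (self-attention, GELU feed-forward,
residual connections, layer norm) produces features `h ∈ R^{n×d}`. All
inputs are single sentences, so the segment id is constant; the term is kept
for fidelity to the embedding decomposition. The position table is learned,
not sinusoidal, because the relation stage re-reads it (below).

**Stage 1 — subject tagging.** Two per-token sigmoid classifiers
(`σ(W h_t + b)`, width 1) mark subject start and end probabilities. Tags are
`1` where the probability strictly exceeds a threshold `tau_subj` (default
0.5; at exactly 0.5 nothing fires, so an untrained model is silent). Starts
are paired with ends by the nearest-match rule: scanning starts left to
right, each start takes the nearest end at or after it that precedes the
next start; unmatched starts are dropped rather than extended, favouring
entity integrity. End tags mark the inclusive last token; spans are
half-open `[start, end)` everywhere else, converting only at the tagging
boundary.

**Stage 2 — relation–object tagging.** For each subject (every gold subject
during training; every decoded subject at inference), its representation `v`
is the mean of `h` over the span. The pipeline is

```
h → CLN(h; γ(v), β(v)) → + E_P → talking-head attention → O
start/end probabilities = σ(W (O + v) + b)    (width R, one column per relation)
```

*Conditional layer normalization (CLN).* Each token row is standardised —
`(h_t − mean) / (std + ε)` with the population standard deviation and
additive `ε = 1e-6` — then scaled and shifted by `γ(v) = 1 + W_γ v + b_γ`
and `β(v) = W_β v + b_β`. The condition maps are zero-initialised, so CLN
starts as plain layer norm and learns its subject dependence; this
parameterisation was chosen for training stability (the unconditioned limit
is the standard, well-behaved operator). A `1e-12` term inside the square
root keeps the derivative finite on exactly-constant rows, where the output
is 0 regardless.

*Position fusion.* The encoder's own position table `E_P` is re-added after
CLN. A single symbol serves both uses, so one learned table is shared rather
than maintaining a second one.

*Talking-head attention (THA).* Standard per-head scaled dot-product logits
`A_i = Q_i K_iᵀ/√d_k` are mixed across heads by a learned `λ_W` before the
softmax and the resulting weights by a learned `λ_L` after it
(`J = λ_L · softmax(λ_W · A)`); head outputs `J_i V_i` are concatenated and
output-projected. Both λ matrices are initialised to the identity, at which
point THA is *exactly* plain multi-head attention — that identity limit is a
tested invariant and plain MHA serves as the oracle baseline and as the
`no_tha` ablation. With padded batches, masked key logits are set to −1e9
both before and after the λ_W mix (mixing across heads must not resurrect a
padded key), and after the λ_L mix the weights on masked keys are zeroed and
each row renormalised over unmasked keys (a `1e-9` guard on the
denominator). With identity λ this renormalisation divides by 1, preserving
the MHA limit.

*Fusion with the subject.* `v` is broadcast-added to every token row of `O`
before the width-`R` pointer head, keeping all dimensions at `d`.

**Objective.** For gold tag `y` and probability `p`, every start/end
position contributes the Bernoulli log-likelihood `y log p + (1−y) log(1−p)`;
the objective `K` sums these over subject tags and, per traversed gold
subject, over object tags for all `R` relations, over all sentences.
Training maximises `K` (teacher forcing: stage 2 is conditioned on gold
subject spans; predicted spans are used only at inference). Probabilities
are clipped to `[1e-7, 1 − 1e-7]` inside the logarithms. The optimiser
minimises `−K / (number of tag positions)`; the normalisation keeps the
learning rate meaningful across corpus sizes and rescales the objective by a
positive constant only.

## Numerical core

No array autodiff framework is a dependency; the package carries a small
reverse-mode autodiff engine (`casctriple._tensor`) over numpy `float64`
arrays (broadcasting arithmetic, matmul, reductions, gather, softmax, etc.).
Every op's gradient is unit-tested against central finite differences, and
an end-to-end finite-difference check of the full cascade loss is part of
the acceptance suite (agreement to 1e-4 relative on a d=8 model).

## Training procedure

Seeded epoch loop: shuffle, batch (default 8), teacher-forced forward,
backward, global-norm gradient clipping at 1.0, Adam step. The learning
rate is halved after 3 epochs without relative improvement above `tol`
(plateau rule — the stopping signal is the objective itself), and training
stops at *steady state*: no relative improvement above `tol = 1e-4` within
the last `patience = 5` epochs, or when the epoch budget is exhausted. The
best-loss parameters are restored at the end. One integer seed fixes
initialisation, data order and dropout, making runs bit-reproducible.

Defaults are desk-scale: hidden size 64, 2 encoder blocks, 4 encoder heads,
8 talking heads, dropout 0, learning rate 1e-3 — sized so a full study runs
in minutes on one CPU core. The full-scale profile of the original setting
(12 blocks, width 768, 48 talking heads, lr 1e-5, batch 8, max length 128)
is exposed as `ModelConfig.full_scale()` / `TrainConfig.full_scale()`; it is
a configuration of the same architecture, not a different code path, but is
not exercised by the tests. A pretrained-encoder adapter seam
(`encoder.load_pretrained_adapter`) loads externally produced encoder
weights from an `.npz` checkpoint and raises rather than silently falling
back when the checkpoint is absent.

## Evaluation

A predicted triplet is correct iff its (subject surface, predicate, object
surface) exactly equals a gold triplet, matched one-to-one after gold
deduplication; precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their
harmonic mean, 0 on empty denominators (a span-strict mode is available via
a flag). Sentences are partitioned by gold overlap structure: **EPO** if two
triplets share the same *ordered* (subject, object) pair (the taxonomy does
not fix ordered vs unordered; ordered is this package's convention),
else **SEO** if two triplets share at least one entity, else **Normal**;
EPO takes precedence so the partition is exclusive.

## Synthetic data generator

The generator (`casctriple.synthetic`) emulates the spo-list JSONL dialect:
character sentences containing multi-character entity mentions, a fixed
relation schema, and an exactly realised Normal/EPO/SEO mix (largest-
remainder apportionment of the requested proportions).

Design: four entity lexical classes with pairwise-disjoint CJK alphabets —
subject classes A, B and object classes X, Y — plus a disjoint distractor
alphabet, so a character identifies its class. The relation between classes
is the deterministic rule `r = (2·class(s) + class(o)) mod R`; the
designated EPO pair (B, Y) always carries that relation *and* its successor
mod R. A subject relates to exactly the objects between it and the next
subject (adjacency pairing). Sentences are laid out subject-first per group
with 1–3 distractor characters between mentions (`distractor_rate` scales
run lengths); half of Normal sentences carry two disjoint subject–object
groups so that stage 2 must actually condition on the subject rather than
tag every compatible object. Surfaces are sampled without replacement per
sentence (lexicon of 40 pseudo-words per class, lengths 2–4) and a sentence
is resampled if any surface's first occurrence differs from its placed span,
so offset-free round-trips through the JSONL dialect are lossless.

Because gold triplets are a deterministic function of the text, the
Bayes-optimal exact-match F1 is 1.0, and a desk-scale model trained from
scratch approaches it. What the generator does **not** emulate: real lexical
statistics and spelling variation, relation semantics that require world
knowledge rather than lexical class, annotation noise, long-range
subject–object dependencies, and nested or discontinuous mentions. Passing
the synthetic recovery check therefore demonstrates that the architecture,
objective, decoding and evaluation machinery are implemented coherently and
can represent and learn overlapping-triplet structure — not that the model
reaches any particular accuracy on real clinical corpora.

## Canonical study sizes

`casctriple.protocols` fixes the problem sizes used by the acceptance
script and tests, chosen so the whole study runs in a few minutes on one
CPU core:

* **Recovery**: 1000 generated sentences (mix 0.5/0.25/0.25, R = 4), split
  800 train / 200 held-out — the held-out block is an untrained split of the
  same corpus, so train and test share the entity lexicon while sentences
  are disjoint; desk-scale model, up to 40 epochs.
* **EPO ablation**: EPO-heavy mix 0.1/0.8/0.1, 400 sentences split 300/100;
  full model vs `no_tha` under identical seeds, median EPO-class F1 over
  3 seeds, 25 epochs each.

## Known limitations

* Decoded subjects are not monotone in the threshold: lowering `tau` adds
  candidate start/end *tags* monotonically, but next-start fencing can then
  re-pair spans. The convention when two starts share one nearest end
  (the earlier start is fenced off and dropped) is this package's choice;
  the nearest-match rule itself does not specify it.
* First-occurrence span resolution is a convention for corpora that omit
  offsets; sentences where a gold surface recurs earlier than its intended
  mention are silently resolved to the first occurrence.
* The Bernoulli likelihood treats tag positions independently; no CRF-style
  span consistency is enforced beyond the matching rule.
* Training is single-threaded, full-precision, CPU-bound; the full-scale
  profile is impractical without substituting a pretrained encoder through
  the adapter seam.
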