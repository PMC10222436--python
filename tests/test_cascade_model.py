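"""Cascade assembly: subject tagging, subject vectors, the conditioned
relation-object pipeline, and the objective."""

import numpy as np
import pytest

from casctriple._tensor import Tensor
from casctriple.corpus import RelationSchema
from casctriple.encoder import Vocabulary
from casctriple.layers import (layer_norm_stats, make_condition,
                               conditional_layer_norm, multi_head_attention,
                               pointer_probabilities)
from casctriple.model import (CascadeTagger, ModelConfig, SubjectSpan,
                              bernoulli_log_likelihood, build_gold_tags,
                              loss_K)
from casctriple.corpus import annotate


@pytest.fixture
def tiny_model():
    schema = RelationSchema(("P0", "P1"))
    vocab = Vocabulary(list("abcdef"))
    cfg = ModelConfig(hidden_size=16, n_blocks=1, n_encoder_heads=2,
                      tha_heads=2, max_length=16)
    return CascadeTagger(cfg, schema, vocab, seed=3)


def _encode(model, text):
    return model.encode(model.vocab.encode(list(text)))


def test_forward_subjects_shape_and_determinism(tiny_model):
    enc = _encode(tiny_model, "abcd")
    s1, e1 = tiny_model.forward_subjects(enc)
    s2, e2 = tiny_model.forward_subjects(enc)
    assert s1.data.shape == (4,) and e1.data.shape == (4,)
    assert np.array_equal(s1.data, s2.data)
    assert ((0 < s1.data) & (s1.data < 1)).all()


def test_zero_weight_subject_head_gives_half(tiny_model):
    for p in tiny_model.subject_head.parameters():
        p.data = np.zeros_like(p.data)
    s, e = tiny_model.forward_subjects(_encode(tiny_model, "abc"))
    assert np.allclose(s.data, 0.5) and np.allclose(e.data, 0.5)


def test_subject_vector_is_span_mean(tiny_model, rng):
    enc = _encode(tiny_model, "abcdef")
    h = enc.h.data
    assert np.allclose(
        tiny_model.subject_vector(enc, SubjectSpan(2, 3)).data, h[2])
    assert np.allclose(
        tiny_model.subject_vector(enc, SubjectSpan(1, 3)).data, (h[1] + h[2]) / 2)
    for _ in range(5):
        a = int(rng.integers(0, 5))
        b = int(rng.integers(a + 1, 7))
        brute = sum(h[i] for i in range(a, b)) / (b - a)
        assert np.allclose(
            tiny_model.subject_vector(enc, SubjectSpan(a, b)).data, brute)


def test_empty_span_rejected():
    with pytest.raises(ValueError):
        SubjectSpan(3, 3)


def test_forward_relations_shape_and_range(tiny_model):
    enc = _encode(tiny_model, "abcd")
    start, end = tiny_model.forward_relations(enc, SubjectSpan(0, 2))
    assert start.data.shape == (4, 2) and end.data.shape == (4, 2)
    assert ((0 < start.data) & (start.data < 1)).all()


def test_different_subjects_give_different_object_probs(tiny_model):
    enc = _encode(tiny_model, "abcdef")
    # make the condition maps non-trivial so CLN actually conditions
    r = np.random.default_rng(0)
    for p in tiny_model.condition_maps.parameters():
        p.data = r.normal(0, 0.3, p.data.shape)
    s1, _ = tiny_model.forward_relations(enc, SubjectSpan(0, 2))
    s2, _ = tiny_model.forward_relations(enc, SubjectSpan(3, 5))
    assert not np.allclose(s1.data, s2.data)


def test_relation_pipeline_matches_composed_oracle(tiny_model):
    """Zero-init CLN maps + identity lambdas: pipeline == layer norm ->
    +position -> plain multi-head attention -> pointer head, composed
    independently from the public layer functions."""
    enc = _encode(tiny_model, "face")
    span = SubjectSpan(1, 3)
    start, end = tiny_model.forward_relations(enc, span)

    v = tiny_model.subject_vector(enc, span)
    cond = make_condition(v, tiny_model.condition_maps)
    hhat = conditional_layer_norm(enc.h, cond, eps=tiny_model.config.cln_eps)
    assert np.allclose(
        hhat.data, layer_norm_stats(enc.h, tiny_model.config.cln_eps).data)
    H = hhat.data + tiny_model.encoder.position_table.data[:4]
    O = multi_head_attention(Tensor(H), tiny_model.tha,
                             tiny_model.config.tha_heads,
                             mask=enc.mask).data
    feats = O + v.data
    exp_start, exp_end = pointer_probabilities(Tensor(feats),
                                               tiny_model.relation_head)
    assert np.allclose(start.data, exp_start.data, atol=1e-10)
    assert np.allclose(end.data, exp_end.data, atol=1e-10)


# ---------------------------------------------------------------------------
# objective


def test_perfect_predictions_give_near_zero_loss():
    eps = 1e-9
    gold_s = (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))
    probs_s = (np.where(gold_s[0] > 0, 1 - eps, eps),
               np.where(gold_s[1] > 0, 1 - eps, eps))
    gold_o = np.zeros((3, 2))
    gold_o[2, 1] = 1
    probs_o = np.where(gold_o > 0, 1 - eps, eps)
    loss = loss_K(probs_s, gold_s, [(probs_o, probs_o)], [(gold_o, gold_o)])
    assert abs(loss.item()) < 1e-5


def test_uniform_probabilities_closed_form():
    # all p = 0.5 over L positions and k outputs: each term costs log 2
    L, R = 7, 3
    half = np.full(L, 0.5)
    half_m = np.full((L, R), 0.5)
    gold_s = (np.zeros(L), np.zeros(L))
    gold_o = (np.zeros((L, R)), np.zeros((L, R)))
    loss = loss_K((half, half), gold_s, [(half_m, half_m)], [gold_o])
    expected = (2 * L + 2 * L * R) * np.log(2)
    assert np.isclose(loss.item(), expected, rtol=1e-12)


def test_loss_matches_double_loop_bce_oracle(rng):
    for _ in range(10):
        L = int(rng.integers(1, 8))
        R = int(rng.integers(1, 4))
        ps = rng.uniform(0.01, 0.99, L)
        pe = rng.uniform(0.01, 0.99, L)
        ts = rng.integers(0, 2, L).astype(float)
        te = rng.integers(0, 2, L).astype(float)
        po_s = rng.uniform(0.01, 0.99, (L, R))
        po_e = rng.uniform(0.01, 0.99, (L, R))
        to_s = rng.integers(0, 2, (L, R)).astype(float)
        to_e = rng.integers(0, 2, (L, R)).astype(float)

        expected = 0.0
        for p, t in ((ps, ts), (pe, te)):
            for i in range(L):
                expected -= t[i] * np.log(p[i]) + (1 - t[i]) * np.log(1 - p[i])
        for p, t in ((po_s, to_s), (po_e, to_e)):
            for i in range(L):
                for r in range(R):
                    expected -= (t[i, r] * np.log(p[i, r])
                                 + (1 - t[i, r]) * np.log(1 - p[i, r]))
        got = loss_K((ps, pe), (ts, te), [(po_s, po_e)], [(to_s, to_e)])
        assert np.isclose(got.item(), expected, rtol=1e-6)


def test_loss_additive_over_sentences(rng):
    def rand_instance():
        L = int(rng.integers(2, 6))
        ps = (rng.uniform(0.1, 0.9, L), rng.uniform(0.1, 0.9, L))
        ts = (rng.integers(0, 2, L).astype(float),
              rng.integers(0, 2, L).astype(float))
        return ps, ts

    (p1, t1), (p2, t2) = rand_instance(), rand_instance()
    la = loss_K(p1, t1, [], []).item()
    lb = loss_K(p2, t2, [], []).item()
    combined = loss_K(
        (np.concatenate([p1[0], p2[0]]), np.concatenate([p1[1], p2[1]])),
        (np.concatenate([t1[0], t2[0]]), np.concatenate([t1[1], t2[1]])),
        [], []).item()
    assert np.isclose(la + lb, combined, rtol=1e-12)


def test_gradient_check_finite_difference(rng):
    """Autodiff gradient of the full cascade loss vs central differences."""
    schema = RelationSchema(("P0", "P1"))
    vocab = Vocabulary(list("ab"))
    cfg = ModelConfig(hidden_size=8, n_blocks=1, n_encoder_heads=2,
                      tha_heads=2, max_length=8)
    model = CascadeTagger(cfg, schema, vocab, seed=1)
    sent = annotate("abab", [
        {"subject": "a", "predicate": "P0", "object": "b"}], schema)
    gold = build_gold_tags(sent, schema)
    ids = vocab.encode(sent.tokens)

    def full_loss():
        enc = model.encode(ids)
        s_start, s_end = model.forward_subjects(enc)
        k = bernoulli_log_likelihood(s_start, gold.subj_start) + \
            bernoulli_log_likelihood(s_end, gold.subj_end)
        for span, os_, oe_ in zip(gold.subjects, gold.obj_start, gold.obj_end):
            o_s, o_e = model.forward_relations(enc, span)
            k = k + bernoulli_log_likelihood(o_s, os_) + \
                bernoulli_log_likelihood(o_e, oe_)
        return -k

    loss = full_loss()
    from casctriple import nn
    params = model.parameters()
    nn.zero_grads(params)
    loss.backward()

    checked = 0
    r = np.random.default_rng(5)
    for p in [model.tha.lambda_W, model.condition_maps.w_gamma,
              model.encoder.tables.token_table, model.subject_head.w_start,
              model.relation_head.w_end, model.encoder.blocks[0].w_ff1]:
        flat_idx = int(r.integers(p.data.size))
        idx = np.unravel_index(flat_idx, p.data.shape)
        eps = 1e-5
        orig = p.data[idx]
        p.data[idx] = orig + eps
        hi = full_loss().item()
        p.data[idx] = orig - eps
        lo = full_loss().item()
        p.data[idx] = orig
        fd = (hi - lo) / (2 * eps)
        auto = p.grad[idx] if p.grad is not None else 0.0
        denom = max(abs(fd), abs(auto), 1e-8)
        assert abs(fd - auto) / denom < 1e-4, (fd, auto)
        checked += 1
    assert checked == 6


def test_gold_tags_traverse_every_subject(schema4, small_corpus):
    for sent in small_corpus[:20]:
        gold = build_gold_tags(sent, schema4)
        distinct_subjects = {t.subject_span for t in sent.triplets}
        assert len(gold.subjects) == len(distinct_subjects)
        assert gold.subj_start.sum() >= 1


def test_checkpoint_roundtrip(tmp_path, tiny_model):
    enc = _encode(tiny_model, "abc")
    before = tiny_model.forward_subjects(enc)[0].data
    path = tmp_path / "model.npz"
    tiny_model.save(path)
    loaded = CascadeTagger.load(path)
    after = loaded.forward_subjects(_encode(loaded, "abc"))[0].data
    assert np.allclose(before, after)
    assert loaded.schema == tiny_model.schema
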