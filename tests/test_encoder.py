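"""Embedding sum, transformer stack behaviour, pretrained adapter seam."""

import numpy as np
import pytest

from casctriple.encoder import (EmbeddingTables, Encoder, EncoderConfig,
                                PretrainedUnavailableError, Vocabulary, embed,
                                load_pretrained_adapter,
                                save_encoder_checkpoint)
from casctriple import nn


@pytest.fixture
def tiny_encoder(rng):
    vocab = Vocabulary(list("abcdef"))
    cfg = EncoderConfig(hidden_size=32, n_blocks=2, n_encoder_heads=4,
                        max_length=16)
    return Encoder.init(rng, vocab, cfg)


def test_embed_is_sum_of_three_table_rows(rng):
    tables = EmbeddingTables.init(rng, vocab_size=5, d=4, max_length=8)
    ids = np.array([3])
    out = embed(ids, tables).data
    expected = (tables.token_table.data[3] + tables.segment_table.data[0]
                + tables.position_table.data[0])
    assert np.allclose(out[0], expected)


def test_embed_zero_tables_give_zero_matrix():
    tables = EmbeddingTables(nn.zeros((5, 4)), nn.zeros((2, 4)), nn.zeros((8, 4)))
    assert np.allclose(embed(np.array([0, 1, 2]), tables).data, 0.0)


def test_identical_tokens_differ_by_position_rows(rng):
    tables = EmbeddingTables.init(rng, vocab_size=5, d=4, max_length=8)
    out = embed(np.array([2, 2]), tables).data
    diff = tables.position_table.data[1] - tables.position_table.data[0]
    assert np.allclose(out[1] - out[0], diff)


def test_embed_rejects_overlong_input(rng):
    tables = EmbeddingTables.init(rng, vocab_size=5, d=4, max_length=3)
    with pytest.raises(ValueError, match="exceeds"):
        embed(np.zeros(4, dtype=np.int64), tables)


def test_zeroed_block_reduces_to_layer_norm(rng):
    vocab = Vocabulary(list("ab"))
    cfg = EncoderConfig(hidden_size=8, n_blocks=1, n_encoder_heads=2, max_length=8)
    enc = Encoder.init(rng, vocab, cfg)
    blk = enc.blocks[0]
    for p in blk.attn.parameters() + [blk.w_ff1, blk.b_ff1, blk.w_ff2, blk.b_ff2]:
        p.data = np.zeros_like(p.data)
    ids = enc.vocab.encode(list("ab"))
    out = enc.encode(ids).h.data
    x = embed(ids, enc.tables).data
    normed = (x - x.mean(1, keepdims=True)) / (x.std(1, keepdims=True) + cfg.ln_eps)
    # residual-only block: LN2(LN1(x)); LN of an already-normalised input is itself
    assert np.allclose(out, normed, atol=1e-4)


def test_encode_shapes_and_finiteness(tiny_encoder):
    ids = tiny_encoder.vocab.encode(list("abcab"))
    out = tiny_encoder.encode(ids)
    assert out.h.data.shape == (5, 32)
    assert np.isfinite(out.h.data).all()


def test_encode_deterministic_in_eval_mode(tiny_encoder):
    ids = tiny_encoder.vocab.encode(list("fedc"))
    h1 = tiny_encoder.encode(ids).h.data
    h2 = tiny_encoder.encode(ids).h.data
    assert np.array_equal(h1, h2)


def test_masked_tokens_do_not_affect_unmasked_outputs(tiny_encoder):
    ids1 = tiny_encoder.vocab.encode(list("abcd"))
    ids2 = ids1.copy()
    ids2[3] = tiny_encoder.vocab.encode(["f"])[0]
    mask = np.array([1, 1, 1, 0], dtype=bool)
    h1 = tiny_encoder.encode(ids1, mask=mask).h.data
    h2 = tiny_encoder.encode(ids2, mask=mask).h.data
    assert np.allclose(h1[:3], h2[:3])


def test_vocabulary_permutation_invariance(rng):
    """Permuting vocab ids together with the token table leaves h unchanged."""
    chars = list("abcd")
    cfg = EncoderConfig(hidden_size=8, n_blocks=1, n_encoder_heads=2, max_length=8)
    enc = Encoder.init(rng, Vocabulary(chars), cfg)
    ids = enc.vocab.encode(list("dcba"))
    h_ref = enc.encode(ids).h.data

    perm = rng.permutation(len(enc.vocab))
    inv = np.argsort(perm)
    # relabel id i as perm[i]; row perm[i] of the new table is row i of the old
    enc.tables.token_table.data = enc.tables.token_table.data[inv]
    h_perm = enc.encode(perm[ids]).h.data
    assert np.allclose(h_ref, h_perm)


def test_dropout_only_in_training_mode(rng):
    vocab = Vocabulary(list("ab"))
    cfg = EncoderConfig(hidden_size=8, n_blocks=1, n_encoder_heads=2,
                        max_length=8, dropout=0.5)
    enc = Encoder.init(rng, vocab, cfg)
    ids = enc.vocab.encode(list("ab"))
    eval1 = enc.encode(ids).h.data
    eval2 = enc.encode(ids).h.data
    assert np.array_equal(eval1, eval2)
    r = np.random.default_rng(0)
    train1 = enc.encode(ids, train=True, rng=r).h.data
    train2 = enc.encode(ids, train=True, rng=r).h.data
    assert not np.array_equal(train1, train2)


# -- pretrained adapter seam --------------------------------------------------


def test_absent_checkpoint_errors_not_fallback():
    cfg = EncoderConfig(hidden_size=8, n_blocks=1, n_encoder_heads=2)
    with pytest.raises(PretrainedUnavailableError, match="unavailable"):
        load_pretrained_adapter("/nonexistent/ckpt.npz", cfg)


def test_tiny_checkpoint_roundtrip(tmp_path, tiny_encoder):
    path = tmp_path / "enc.npz"
    save_encoder_checkpoint(tiny_encoder, path)
    loaded = load_pretrained_adapter(path, tiny_encoder.config)
    ids = tiny_encoder.vocab.encode(list("abc"))
    assert np.allclose(tiny_encoder.encode(ids).h.data,
                       loaded.encode(ids).h.data)


def test_checkpoint_dimension_mismatch_rejected(tmp_path, tiny_encoder):
    path = tmp_path / "enc.npz"
    save_encoder_checkpoint(tiny_encoder, path)
    bad = EncoderConfig(hidden_size=64, n_blocks=2, n_encoder_heads=4)
    with pytest.raises(ValueError, match="hidden size"):
        load_pretrained_adapter(path, bad)
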