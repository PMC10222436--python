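"""Contextual sentence encoder.

Characters are mapped to the sum of token, segment and position embeddings
(x_t = E_S + E_T + E_P) and passed through a stack of post-norm transformer
blocks (self-attention + feed-forward, residual connections, layer norm).
The learned position table is exposed because the relation-object stage
re-adds the same position embeddings after conditional layer normalization.

The full-scale configuration in the original setting is a pretrained
12-block, 768-wide, character-level RoBERTa; that is a configuration of this
module, not a different architecture.  The desk-scale default (d=64,
2 blocks, 4 heads, vocabulary built from the corpus) trains from scratch in
seconds on a CPU.  An adapter seam for loading externally produced encoder
weights is provided and fails loudly when the checkpoint is absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._tensor import Tensor, gelu
from . import nn
from .layers import TalkingHeadWeights, layer_norm_stats, multi_head_attention

PAD, UNK = "<pad>", "<unk>"


class PretrainedUnavailableError(FileNotFoundError):
    """Raised when a requested pretrained encoder checkpoint cannot be loaded."""


@dataclass(frozen=True)
class EncoderConfig:
    hidden_size: int = 64
    n_blocks: int = 2
    n_encoder_heads: int = 4
    max_length: int = 128
    ffn_multiplier: int = 4
    dropout: float = 0.0
    ln_eps: float = 1e-6
    pretrained: str | None = None


class Vocabulary:
    """Character vocabulary with reserved PAD (0) and UNK (1) ids."""

    def __init__(self, chars: list[str] | tuple[str, ...] = ()):
        ordered = [PAD, UNK] + sorted(set(chars) - {PAD, UNK})
        self._id = {c: i for i, c in enumerate(ordered)}
        self._chars = ordered

    @classmethod
    def from_corpus(cls, sentences) -> "Vocabulary":
        chars: set[str] = set()
        for s in sentences:
            chars.update(s.tokens)
        return cls(sorted(chars))

    def __len__(self) -> int:
        return len(self._chars)

    @property
    def chars(self) -> list[str]:
        return list(self._chars)

    def encode(self, tokens) -> np.ndarray:
        unk = self._id[UNK]
        return np.array([self._id.get(t, unk) for t in tokens], dtype=np.int64)


@dataclass
class EmbeddingTables:
    token_table: Tensor     # [vocab, d]
    segment_table: Tensor   # [2, d]
    position_table: Tensor  # [max_length, d]

    @classmethod
    def init(cls, rng: np.random.Generator, vocab_size: int, d: int,
             max_length: int) -> "EmbeddingTables":
        return cls(nn.normal(rng, (vocab_size, d)),
                   nn.normal(rng, (2, d)),
                   nn.normal(rng, (max_length, d)))

    def parameters(self):
        return [self.token_table, self.segment_table, self.position_table]


def embed(token_ids: np.ndarray, tables: EmbeddingTables) -> Tensor:
    """x_t = token_table[id_t] + segment_table[0] + position_table[t].

    ``token_ids`` may be ``[n]`` or a padded batch ``[B, n]``.  All inputs are
    single sentences, so the segment id is 0 everywhere (kept in the sum for
    fidelity to the embedding decomposition).
    """
    ids = np.asarray(token_ids)
    n = ids.shape[-1]
    if n > tables.position_table.shape[0]:
        raise ValueError(
            f"sequence length {n} exceeds position table {tables.position_table.shape[0]}")
    tok = tables.token_table[ids]
    seg = tables.segment_table[np.zeros(n, dtype=np.int64)]
    pos = tables.position_table[np.arange(n)]
    return tok + seg + pos


@dataclass
class EncoderBlock:
    attn: TalkingHeadWeights
    ln1_gamma: Tensor
    ln1_beta: Tensor
    w_ff1: Tensor
    b_ff1: Tensor
    w_ff2: Tensor
    b_ff2: Tensor
    ln2_gamma: Tensor
    ln2_beta: Tensor

    @classmethod
    def init(cls, rng, d: int, n_heads: int, ffn_multiplier: int) -> "EncoderBlock":
        dff = ffn_multiplier * d
        return cls(
            attn=TalkingHeadWeights.init(rng, d, n_heads, talking=False),
            ln1_gamma=nn.ones(d), ln1_beta=nn.zeros(d),
            w_ff1=nn.glorot(rng, d, dff), b_ff1=nn.zeros(dff),
            w_ff2=nn.glorot(rng, dff, d), b_ff2=nn.zeros(d),
            ln2_gamma=nn.ones(d), ln2_beta=nn.zeros(d),
        )

    def parameters(self):
        return (self.attn.parameters() +
                [self.ln1_gamma, self.ln1_beta, self.w_ff1, self.b_ff1,
                 self.w_ff2, self.b_ff2, self.ln2_gamma, self.ln2_beta])


@dataclass
class EncodedSentence:
    h: Tensor            # [n, d] or [B, n, d]
    mask: np.ndarray     # [n] or [B, n] boolean


def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rate <= 0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * keep


def encode_blocks(embedded: Tensor, blocks: list[EncoderBlock], n_heads: int,
                  mask: np.ndarray | None = None, eps: float = 1e-6,
                  dropout: float = 0.0,
                  rng: np.random.Generator | None = None) -> Tensor:
    """Post-norm transformer stack: x <- LN(x + Attn(x)); x <- LN(x + FFN(x))."""
    x = embedded
    for blk in blocks:
        a = multi_head_attention(x, blk.attn, n_heads, mask=mask)
        a = _dropout(a, dropout, rng)
        x = layer_norm_stats(x + a, eps) * blk.ln1_gamma + blk.ln1_beta
        f = gelu(x @ blk.w_ff1 + blk.b_ff1) @ blk.w_ff2 + blk.b_ff2
        f = _dropout(f, dropout, rng)
        x = layer_norm_stats(x + f, eps) * blk.ln2_gamma + blk.ln2_beta
    return x


@dataclass
class Encoder:
    """Embedding tables plus the transformer stack, with its config."""

    config: EncoderConfig
    vocab: Vocabulary
    tables: EmbeddingTables
    blocks: list[EncoderBlock]

    @classmethod
    def init(cls, rng: np.random.Generator, vocab: Vocabulary,
             config: EncoderConfig) -> "Encoder":
        d = config.hidden_size
        tables = EmbeddingTables.init(rng, len(vocab), d, config.max_length)
        blocks = [EncoderBlock.init(rng, d, config.n_encoder_heads,
                                    config.ffn_multiplier)
                  for _ in range(config.n_blocks)]
        return cls(config, vocab, tables, blocks)

    def parameters(self):
        ps = self.tables.parameters()
        for blk in self.blocks:
            ps += blk.parameters()
        return ps

    @property
    def position_table(self) -> Tensor:
        return self.tables.position_table

    def encode(self, token_ids: np.ndarray, mask: np.ndarray | None = None,
               train: bool = False,
               rng: np.random.Generator | None = None) -> EncodedSentence:
        """Encode padded token ids ``[n]`` or ``[B, n]`` into features h."""
        ids = np.asarray(token_ids)
        if mask is None:
            mask = ids != 0
        x = embed(ids, self.tables)
        h = encode_blocks(x, self.blocks, self.config.n_encoder_heads,
                          mask=mask, eps=self.config.ln_eps,
                          dropout=self.config.dropout if train else 0.0,
                          rng=rng if train else None)
        return EncodedSentence(h=h, mask=np.asarray(mask, dtype=bool))


def load_pretrained_adapter(name_or_path: str | Path,
                            config: EncoderConfig) -> Encoder:
    """Load externally produced encoder weights from an ``.npz`` checkpoint.

    The checkpoint must contain ``token_table``, ``segment_table``,
    ``position_table``, a ``chars`` array, and per-block weight arrays
    ``block{i}.<name>``.  An absent checkpoint raises
    :class:`PretrainedUnavailableError`; there is no silent fallback to
    random initialisation.
    """
    path = Path(name_or_path)
    if not path.exists():
        raise PretrainedUnavailableError(
            f"pretrained encoder unavailable: no checkpoint at {path}")
    with np.load(path, allow_pickle=False) as ckpt:
        d = ckpt["token_table"].shape[1]
        if d != config.hidden_size:
            raise ValueError(
                f"checkpoint hidden size {d} != configured {config.hidden_size}")
        vocab = Vocabulary([str(c) for c in ckpt["chars"]])
        if ckpt["token_table"].shape[0] != len(vocab):
            raise ValueError("checkpoint vocabulary and token table disagree")
        tables = EmbeddingTables(nn.Parameter(ckpt["token_table"]),
                                 nn.Parameter(ckpt["segment_table"]),
                                 nn.Parameter(ckpt["position_table"]))
        blocks = []
        for i in range(config.n_blocks):
            prefix = f"block{i}."
            try:
                blocks.append(EncoderBlock(
                    attn=TalkingHeadWeights(
                        nn.Parameter(ckpt[prefix + "q"]), nn.Parameter(ckpt[prefix + "k"]),
                        nn.Parameter(ckpt[prefix + "v"]), nn.Parameter(ckpt[prefix + "o"])),
                    ln1_gamma=nn.Parameter(ckpt[prefix + "ln1_gamma"]),
                    ln1_beta=nn.Parameter(ckpt[prefix + "ln1_beta"]),
                    w_ff1=nn.Parameter(ckpt[prefix + "w_ff1"]),
                    b_ff1=nn.Parameter(ckpt[prefix + "b_ff1"]),
                    w_ff2=nn.Parameter(ckpt[prefix + "w_ff2"]),
                    b_ff2=nn.Parameter(ckpt[prefix + "b_ff2"]),
                    ln2_gamma=nn.Parameter(ckpt[prefix + "ln2_gamma"]),
                    ln2_beta=nn.Parameter(ckpt[prefix + "ln2_beta"]),
                ))
            except KeyError as exc:
                raise ValueError(f"checkpoint missing weights for block {i}") from exc
    return Encoder(config, vocab, tables, blocks)


def save_encoder_checkpoint(encoder: Encoder, path: str | Path) -> None:
    arrays: dict[str, np.ndarray] = {
        "token_table": encoder.tables.token_table.data,
        "segment_table": encoder.tables.segment_table.data,
        "position_table": encoder.tables.position_table.data,
        "chars": np.array(encoder.vocab.chars),
    }
    for i, blk in enumerate(encoder.blocks):
        prefix = f"block{i}."
        arrays[prefix + "q"] = blk.attn.q_proj.data
        arrays[prefix + "k"] = blk.attn.k_proj.data
        arrays[prefix + "v"] = blk.attn.v_proj.data
        arrays[prefix + "o"] = blk.attn.out_proj.data
        arrays[prefix + "ln1_gamma"] = blk.ln1_gamma.data
        arrays[prefix + "ln1_beta"] = blk.ln1_beta.data
        arrays[prefix + "w_ff1"] = blk.w_ff1.data
        arrays[prefix + "b_ff1"] = blk.b_ff1.data
        arrays[prefix + "w_ff2"] = blk.w_ff2.data
        arrays[prefix + "b_ff2"] = blk.b_ff2.data
        arrays[prefix + "ln2_gamma"] = blk.ln2_gamma.data
        arrays[prefix + "ln2_beta"] = blk.ln2_beta.data
    np.savez(path, **arrays)
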