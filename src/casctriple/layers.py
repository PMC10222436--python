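"""The model's bespoke layers.

* conditional layer normalization (CLN): per-token layer norm whose scale
  gamma and shift beta are affine functions of a conditioning vector (here,
  the subject representation).  With zero-initialised condition projections
  it reduces exactly to plain layer norm, which is how it is initialised.
* talking-head attention (THA): multi-head attention augmented with two
  learned head-mixing matrices, lambda_W applied to the attention logits
  (pre-softmax) and lambda_L applied to the attention weights (post-softmax).
  With both lambdas set to the identity it coincides with plain multi-head
  attention, which serves as its oracle baseline.
* sigmoid pointer heads: per-token start/end probability projections of
  width 1 (subject tagger) or R (per-relation object tagger).

All functions accept ``Tensor`` (differentiable) or raw arrays and operate
on ``[n, d]`` single sentences or ``[B, n, d]`` batches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor, sigmoid, softmax
from . import nn

_NEG = -1e9  # additive mask value for padded keys


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# conditional layer normalization


@dataclass
class CLNCondition:
    """Dynamic scale/shift produced from a subject representation."""

    gamma: Tensor
    beta: Tensor


def layer_norm_stats(h: Tensor, eps: float) -> Tensor:
    """(h - mean) / (std + eps) over the last (feature) axis.

    std is the population (biased) standard deviation; the tiny constant
    inside the square root keeps the derivative finite on exactly-constant
    rows (where the output is 0 regardless).
    """
    mu = h.mean(axis=-1, keepdims=True)
    centered = h - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    std = (var + 1e-12) ** 0.5
    return centered / (std + eps)


def conditional_layer_norm(h, condition: CLNCondition, eps: float = 1e-6) -> Tensor:
    """Normalise each token row of ``h`` and apply the conditional gamma/beta.

    gamma/beta broadcast: ``[d]`` applies everywhere, ``[B, d]`` applies one
    condition per batch item of a ``[B, n, d]`` input.
    """
    h = _as_tensor(h)
    if not np.all(np.isfinite(h.data)):
        raise ValueError("non-finite input to conditional_layer_norm")
    normed = layer_norm_stats(h, eps)
    gamma, beta = _as_tensor(condition.gamma), _as_tensor(condition.beta)
    if h.ndim == 3 and gamma.ndim == 2:
        gamma = gamma.reshape(gamma.shape[0], 1, gamma.shape[1])
        beta = beta.reshape(beta.shape[0], 1, beta.shape[1])
    return normed * gamma + beta


@dataclass
class ConditionMaps:
    """Learned affine maps d -> d producing gamma = 1 + Wg v + bg, beta = Wb v + bb.

    Zero-initialised, so CLN starts as unconditioned layer norm.
    """

    w_gamma: Tensor
    b_gamma: Tensor
    w_beta: Tensor
    b_beta: Tensor

    @classmethod
    def init(cls, d: int) -> "ConditionMaps":
        return cls(nn.zeros((d, d)), nn.zeros(d), nn.zeros((d, d)), nn.zeros(d))

    def parameters(self):
        return [self.w_gamma, self.b_gamma, self.w_beta, self.b_beta]


def make_condition(subject_vec, maps: ConditionMaps) -> CLNCondition:
    """Map a subject vector (``[d]`` or ``[M, d]``) to a CLN condition."""
    v = _as_tensor(subject_vec)
    gamma = v @ maps.w_gamma + maps.b_gamma + 1.0
    beta = v @ maps.w_beta + maps.b_beta
    return CLNCondition(gamma=gamma, beta=beta)


# ---------------------------------------------------------------------------
# attention


@dataclass
class TalkingHeadWeights:
    """Projections plus the two head-mixing matrices lambda_W / lambda_L.

    ``lambda_W``/``lambda_L`` may be ``None`` for plain multi-head attention.
    """

    q_proj: Tensor
    k_proj: Tensor
    v_proj: Tensor
    out_proj: Tensor
    lambda_W: Tensor | None = None
    lambda_L: Tensor | None = None

    @classmethod
    def init(cls, rng: np.random.Generator, d: int, n_heads: int,
             talking: bool = True) -> "TalkingHeadWeights":
        if d % n_heads:
            raise ValueError(f"n_heads={n_heads} must divide hidden size {d}")
        mk = lambda: nn.glorot(rng, d, d)
        lam_w = nn.identity(n_heads) if talking else None
        lam_l = nn.identity(n_heads) if talking else None
        return cls(mk(), mk(), mk(), mk(), lam_w, lam_l)

    def parameters(self):
        ps = [self.q_proj, self.k_proj, self.v_proj, self.out_proj]
        if self.lambda_W is not None:
            ps += [self.lambda_W, self.lambda_L]
        return ps


def _mix_heads(logits: Tensor, lam: Tensor) -> Tensor:
    """mixed[..., i, :, :] = sum_j lam[i, j] * logits[..., j, :, :].

    ``logits`` is ``[B, h, n, n]``; mixing acts along the head axis only.
    """
    moved = logits.transpose((0, 2, 3, 1))        # [B, n, n, h]
    mixed = moved @ lam.swapaxes(-1, -2)           # right-multiply by lam^T
    return mixed.transpose((0, 3, 1, 2))


def _masked_fill(x: Tensor, keep: np.ndarray, value: float) -> Tensor:
    return x * keep + (1.0 - keep) * value


def _attention(H, w: TalkingHeadWeights, n_heads: int,
               mask: np.ndarray | None = None,
               lambda_W: Tensor | None = None,
               lambda_L: Tensor | None = None) -> Tensor:
    H = _as_tensor(H)
    squeeze = H.ndim == 2
    if squeeze:
        H = H.reshape(1, *H.shape)
    B, n, d = H.shape
    if d % n_heads:
        raise ValueError(f"n_heads={n_heads} must divide hidden size {d}")
    dk = d // n_heads

    def split(x: Tensor) -> Tensor:  # [B, n, d] -> [B, h, n, dk]
        return x.reshape(B, n, n_heads, dk).transpose((0, 2, 1, 3))

    Q = split(H @ w.q_proj)
    K = split(H @ w.k_proj)
    V = split(H @ w.v_proj)

    logits = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))  # [B, h, n, n]

    keep = None
    if mask is not None:
        keep = np.asarray(mask, dtype=np.float64).reshape(B, 1, 1, n)
        logits = _masked_fill(logits, keep, _NEG)
    if lambda_W is not None:
        logits = _mix_heads(logits, lambda_W)
        if keep is not None:
            # head mixing must not resurrect padded keys
            logits = _masked_fill(logits, keep, _NEG)
    weights = softmax(logits, axis=-1)
    if lambda_L is not None:
        weights = _mix_heads(weights, lambda_L)
        if keep is not None:
            weights = weights * keep
            denom = weights.sum(axis=-1, keepdims=True) + 1e-9
            weights = weights / denom

    heads = weights @ V                                       # [B, h, n, dk]
    merged = heads.transpose((0, 2, 1, 3)).reshape(B, n, d)
    out = merged @ w.out_proj
    return out.reshape(n, d) if squeeze else out


def multi_head_attention(H, w: TalkingHeadWeights, n_heads: int,
                         mask: np.ndarray | None = None) -> Tensor:
    """Standard scaled dot-product multi-head attention with output projection."""
    return _attention(H, w, n_heads, mask=mask)


def talking_head_attention(H, w: TalkingHeadWeights, n_heads: int,
                           mask: np.ndarray | None = None) -> Tensor:
    """Multi-head attention with head mixing: J = lambda_L . softmax(lambda_W . A).

    lambda_W mixes attention logits across heads before the softmax and
    lambda_L mixes the attention weights after it; with both equal to the
    identity this is exactly ``multi_head_attention``.
    """
    if w.lambda_W is None or w.lambda_L is None:
        raise ValueError("talking-head attention requires lambda_W and lambda_L")
    return _attention(H, w, n_heads, mask=mask,
                      lambda_W=_as_tensor(w.lambda_W), lambda_L=_as_tensor(w.lambda_L))


# ---------------------------------------------------------------------------
# pointer heads


@dataclass
class PointerHead:
    """Sigmoid start/end taggers: width 1 (subjects) or R (objects per relation)."""

    w_start: Tensor
    b_start: Tensor
    w_end: Tensor
    b_end: Tensor

    @classmethod
    def init(cls, rng: np.random.Generator, d: int, out_width: int) -> "PointerHead":
        return cls(nn.glorot(rng, d, out_width), nn.zeros(out_width),
                   nn.glorot(rng, d, out_width), nn.zeros(out_width))

    def parameters(self):
        return [self.w_start, self.b_start, self.w_end, self.b_end]


def pointer_probabilities(features, head: PointerHead) -> tuple[Tensor, Tensor]:
    """start = sigmoid(features @ W_start + b_start); end likewise."""
    f = _as_tensor(features)
    return (sigmoid(f @ head.w_start + head.b_start),
            sigmoid(f @ head.w_end + head.b_end))
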