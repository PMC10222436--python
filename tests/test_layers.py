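"""Conditional layer norm, attention variants and pointer heads."""

import numpy as np
import pytest

from casctriple._tensor import Tensor, softmax
from casctriple.layers import (CLNCondition, ConditionMaps, PointerHead,
                               TalkingHeadWeights, conditional_layer_norm,
                               make_condition, multi_head_attention,
                               pointer_probabilities, talking_head_attention)

# ---------------------------------------------------------------------------
# conditional layer normalization


def test_cln_unit_condition_standardizes_rows(rng):
    h = rng.normal(2.0, 3.0, (12, 16))
    cond = CLNCondition(Tensor(np.ones(16)), Tensor(np.zeros(16)))
    out = conditional_layer_norm(h, cond, eps=1e-6).data
    assert np.abs(out.mean(axis=1)).max() < 1e-10
    assert np.abs(out.std(axis=1) - 1.0).max() < 1e-4


def test_cln_constant_row_is_zero_not_nan():
    h = np.full((1, 8), 5.0)
    cond = CLNCondition(Tensor(np.ones(8)), Tensor(np.zeros(8)))
    out = conditional_layer_norm(h, cond).data
    assert np.allclose(out, 0.0)


def test_cln_hand_example_two_features():
    # row [1, 3]: population std 1, normalize to [-1, 1]; gamma 2, beta 1 -> [-1, 3]
    cond = CLNCondition(Tensor([2.0, 2.0]), Tensor([1.0, 1.0]))
    out = conditional_layer_norm(np.array([[1.0, 3.0]]), cond).data
    assert np.allclose(out, [[-1.0, 3.0]], atol=1e-4)


def test_cln_rejects_nonfinite_input():
    cond = CLNCondition(Tensor(np.ones(2)), Tensor(np.zeros(2)))
    with pytest.raises(ValueError, match="non-finite"):
        conditional_layer_norm(np.array([[np.nan, 1.0]]), cond)


def test_make_condition_zero_init_is_plain_layer_norm(rng):
    maps = ConditionMaps.init(8)
    cond = make_condition(rng.normal(0, 1, 8), maps)
    assert np.allclose(cond.gamma.data, 1.0)
    assert np.allclose(cond.beta.data, 0.0)


def test_make_condition_affine_identity(rng):
    maps = ConditionMaps.init(6)
    for p in maps.parameters():
        p.data = rng.normal(0, 1, p.data.shape)
    a, b = rng.normal(0, 1, 6), rng.normal(0, 1, 6)
    ca = make_condition(a, maps)
    cb = make_condition(b, maps)
    cab = make_condition(a + b, maps)
    c0 = make_condition(np.zeros(6), maps)
    # affine maps: f(a+b) = f(a) + f(b) - f(0)
    assert np.allclose(cab.beta.data, ca.beta.data + cb.beta.data - c0.beta.data)
    assert np.allclose(cab.gamma.data, ca.gamma.data + cb.gamma.data - c0.gamma.data)


def test_distinct_subjects_give_distinct_conditions(rng):
    maps = ConditionMaps.init(6)
    for p in maps.parameters():
        p.data = rng.normal(0, 1, p.data.shape)
    c1 = make_condition(rng.normal(0, 1, 6), maps)
    c2 = make_condition(rng.normal(0, 1, 6), maps)
    assert not np.allclose(c1.gamma.data, c2.gamma.data)


# ---------------------------------------------------------------------------
# attention


def _random_weights(rng, d, h, talking=True, perturb=0.3):
    w = TalkingHeadWeights.init(rng, d, h, talking=talking)
    if talking and perturb:
        w.lambda_W.data = np.eye(h) + rng.normal(0, perturb, (h, h))
        w.lambda_L.data = np.eye(h) + rng.normal(0, perturb, (h, h))
    return w


def test_single_token_attention_is_projection_chain(rng):
    d = 8
    w = _random_weights(rng, d, 2, talking=False)
    x = rng.normal(0, 1, (1, d))
    out = multi_head_attention(x, w, 2).data
    expected = (x @ w.v_proj.data) @ w.out_proj.data  # softmax of 1x1 logit is 1
    assert np.allclose(out, expected)


def test_softmax_rows_normalize(rng):
    logits = Tensor(rng.normal(0, 3, (4, 7)))
    assert np.allclose(softmax(logits, axis=-1).data.sum(axis=-1), 1.0)


def test_two_token_single_head_matches_scalar_oracle(rng):
    """Hand-computed scaled dot-product attention, d=2, h=1."""
    d, n = 2, 2
    w = _random_weights(rng, d, 1, talking=False)
    H = rng.normal(0, 1, (n, d))
    Q, K, V = H @ w.q_proj.data, H @ w.k_proj.data, H @ w.v_proj.data
    expected = np.zeros((n, d))
    for i in range(n):
        logits = np.array([Q[i] @ K[j] / np.sqrt(d) for j in range(n)])
        e = np.exp(logits - logits.max())
        a = e / e.sum()
        expected[i] = sum(a[j] * V[j] for j in range(n))
    expected = expected @ w.out_proj.data
    assert np.allclose(multi_head_attention(H, w, 1).data, expected)


def test_talking_head_identity_lambda_equals_multi_head(rng):
    for _ in range(30):
        n = int(rng.integers(1, 7))
        h = int(rng.choice([1, 2, 4]))
        d = int(h * rng.integers(2, 9))
        w = _random_weights(rng, d, h, talking=True, perturb=0.0)
        H = rng.normal(0, 1, (n, d))
        a = multi_head_attention(H, w, h).data
        b = talking_head_attention(H, w, h).data
        assert np.abs(a - b).max() <= 1e-5


def test_talking_head_matches_loop_oracle(rng):
    """Brute-force oracle materializing per-head logits and explicit mixing."""
    n, h, dk = 3, 2, 4
    d = h * dk
    w = _random_weights(rng, d, h, talking=True, perturb=0.5)
    H = rng.normal(0, 1, (n, d))
    Q, K, V = H @ w.q_proj.data, H @ w.k_proj.data, H @ w.v_proj.data
    lam_w, lam_l = w.lambda_W.data, w.lambda_L.data
    A = np.zeros((h, n, n))
    for i in range(h):
        Qi = Q[:, i * dk:(i + 1) * dk]
        Ki = K[:, i * dk:(i + 1) * dk]
        A[i] = Qi @ Ki.T / np.sqrt(dk)
    mixed = np.zeros_like(A)
    for i in range(h):
        for j in range(h):
            mixed[i] += lam_w[i, j] * A[j]
    P = np.exp(mixed - mixed.max(axis=-1, keepdims=True))
    P /= P.sum(axis=-1, keepdims=True)
    J = np.zeros_like(P)
    for i in range(h):
        for j in range(h):
            J[i] += lam_l[i, j] * P[j]
    heads = [J[i] @ V[:, i * dk:(i + 1) * dk] for i in range(h)]
    expected = np.concatenate(heads, axis=1) @ w.out_proj.data
    assert np.allclose(talking_head_attention(H, w, h).data, expected)


def test_talking_head_requires_lambda(rng):
    w = _random_weights(rng, 8, 2, talking=False)
    with pytest.raises(ValueError, match="lambda"):
        talking_head_attention(np.zeros((2, 8)), w, 2)


def test_head_count_must_divide_hidden_size(rng):
    with pytest.raises(ValueError, match="divide"):
        TalkingHeadWeights.init(rng, 8, 3)


def test_attention_permutation_equivariance(rng):
    """Without positional content, permuting tokens permutes outputs."""
    n, d, h = 5, 8, 2
    w = _random_weights(rng, d, h, talking=True, perturb=0.4)
    H = rng.normal(0, 1, (n, d))
    perm = rng.permutation(n)
    out = talking_head_attention(H, w, h).data
    out_perm = talking_head_attention(H[perm], w, h).data
    assert np.allclose(out[perm], out_perm)


def test_masked_keys_do_not_influence_output(rng):
    n, d, h = 6, 8, 2
    w = _random_weights(rng, d, h, talking=True, perturb=0.4)
    H1 = rng.normal(0, 1, (n, d))
    H2 = H1.copy()
    H2[4:] = rng.normal(0, 1, (2, d))  # change only masked positions
    mask = np.array([1, 1, 1, 1, 0, 0], dtype=bool)
    out1 = talking_head_attention(H1, w, h, mask=mask).data
    out2 = talking_head_attention(H2, w, h, mask=mask).data
    assert np.allclose(out1[:4], out2[:4])


# ---------------------------------------------------------------------------
# pointer head


def test_pointer_zero_weights_give_half(rng):
    head = PointerHead.init(rng, 4, 3)
    for p in head.parameters():
        p.data = np.zeros_like(p.data)
    start, end = pointer_probabilities(rng.normal(0, 1, (5, 4)), head)
    assert np.allclose(start.data, 0.5) and np.allclose(end.data, 0.5)


def test_pointer_large_bias_saturates(rng):
    head = PointerHead.init(rng, 4, 1)
    for p in (head.w_start, head.w_end):
        p.data = np.zeros_like(p.data)
    head.b_start.data = np.array([10.0])
    head.b_end.data = np.array([10.0])
    start, end = pointer_probabilities(rng.normal(0, 1, (5, 4)), head)
    assert (start.data > 0.9999).all() and (end.data > 0.9999).all()


def test_pointer_scalar_hand_example(rng):
    head = PointerHead.init(rng, 2, 1)
    head.w_start.data = np.array([[1.0], [-1.0]])
    head.b_start.data = np.array([0.0])
    start, _ = pointer_probabilities(np.array([[2.0, 1.0]]), head)
    assert np.isclose(start.data[0, 0], 1 / (1 + np.exp(-1.0)))
    assert np.isclose(start.data[0, 0], 0.7311, atol=1e-4)
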