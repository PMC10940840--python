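"""Numpy/autograd neural primitives: attention, fixup init, conv blocks.

Everything here operates on plain numpy arrays and is differentiable with
HIPS autograd (``autograd.numpy``), which supplies reverse-mode gradients
for the training loop.  Masks are float arrays with 1 at valid positions
and 0 at padding; masked positions carry exactly zero weight / output so
that scores are invariant to the amount of trailing padding.
"""

from __future__ import annotations

import logging
import math

import autograd.numpy as anp
import numpy as np

logger = logging.getLogger(__name__)

NEG_INF = -1e9


def gelu(x):
    # tanh approximation of the Gaussian error linear unit
    return 0.5 * x * (1.0 + anp.tanh(0.7978845608028654 * (x + 0.044715 * x**3)))


def softmax(x, axis=-1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def layer_norm(x, gamma, beta, eps=1e-5):
    """Normalize the last dimension (the model's norm shape)."""
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return gamma * (x - mu) / anp.sqrt(var + eps) + beta


def fixup_init(
    shape,
    layer_position: int,
    layers_per_block: int,
    fan_in: int,
    seed: int = 0,
) -> np.ndarray:
    """Fixup-style weight draw: N(0, (sigma_l / sqrt(n_l))^2).

    ``sigma_l`` is sqrt(2) for the first layer of a residual block,
    sqrt(0.5) for the last, and 1 for interior layers, so each residual
    block's output stays near unit variance at initialization.
    """
    l_r, n_r, n_l = layer_position, layers_per_block, fan_in
    if not (1 <= l_r <= n_r):
        raise ValueError(f"layer position {l_r} outside 1..{n_r}")
    if n_l < 1:
        raise ValueError("fan-in must be >= 1")
    if l_r == 1 and n_r > 1:
        sigma = math.sqrt(2.0)
    elif l_r == n_r:
        sigma = math.sqrt(0.5)
    else:
        sigma = 1.0
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, sigma / math.sqrt(n_l), size=shape)


def fixup_sigma(layer_position: int, layers_per_block: int) -> float:
    if layer_position == 1 and layers_per_block > 1:
        return math.sqrt(2.0)
    if layer_position == layers_per_block:
        return math.sqrt(0.5)
    return 1.0


def scaled_dot_attention(Q, K, V, mask=None):
    """Scaled dot-product attention; returns (output, weights).

    Works on stacks: Q (..., Tq, d), K (..., Tk, d), V (..., Tk, dv);
    ``mask`` (..., Tk) zeros out keys.  Rows whose keys are all masked get
    zero weights and zero output (logged once).
    """
    d = Q.shape[-1]
    scores = anp.matmul(Q, anp.swapaxes(K, -1, -2)) / anp.sqrt(float(d))
    if mask is not None:
        key_mask = anp.expand_dims(mask, -2)  # (..., 1, Tk)
        scores = scores + (1.0 - key_mask) * NEG_INF
        any_valid = anp.sum(mask, axis=-1) > 0  # (...,)
        if not np.all(np.asarray(any_valid)):
            logger.warning("scaled_dot_attention: fully-masked row -> zero output")
    z = scores - anp.max(scores, axis=-1, keepdims=True)
    e = anp.exp(z)
    if mask is not None:
        e = e * anp.expand_dims(mask, -2)
    denom = anp.sum(e, axis=-1, keepdims=True)
    weights = e / anp.maximum(denom, 1e-30)
    return anp.matmul(weights, V), weights


def multi_head_attention(q, k, v, Wq, Wk, Wv, Wo=None, mask=None):
    """Multi-head attention from stacked per-head projections.

    ``Wq``/``Wk``/``Wv`` have shape (n_heads, d_in, d_head); each head runs
    scaled dot-product attention on its projected streams; head outputs are
    concatenated and passed through ``Wo`` (identity when None).
    """
    n_heads = Wq.shape[0]
    if Wq.shape[0] != Wk.shape[0] or Wq.shape[0] != Wv.shape[0]:
        raise ValueError("per-head projection stacks disagree on n_heads")
    # (n_heads, Tq, d_head)
    qh = anp.einsum("td,hdp->htp", q, Wq)
    kh = anp.einsum("td,hdp->htp", k, Wk)
    vh = anp.einsum("td,hdp->htp", v, Wv)
    out, _w = scaled_dot_attention(qh, kh, vh, mask=mask)
    concat = anp.reshape(anp.transpose(out, (1, 0, 2)), (q.shape[0], -1))
    if Wo is not None:
        concat = anp.dot(concat, Wo)
    return concat


def batched_mha(x_q, x_kv, params, prefix, n_heads, mask_kv=None,
                dropout=0.0, rng=None, collect=None):
    """Batched multi-head attention used inside the transformer blocks.

    ``x_q`` (B, Tq, H), ``x_kv`` (B, Tk, H); combined projection matrices
    ``{prefix}_Wq/Wk/Wv/Wo`` of shape (H, H) are split into heads.  Returns
    (B, Tq, H).  When ``collect`` is a list, per-head weight tensors
    (B, n_heads, Tq, Tk) are appended to it (evaluation-only path).
    """
    B, Tq, H = x_q.shape
    Tk = x_kv.shape[1]
    dh = H // n_heads

    def split(x, W, b):
        y = anp.matmul(x, W) + b  # (B, T, H)
        y = anp.reshape(y, (B, -1, n_heads, dh))
        return anp.transpose(y, (0, 2, 1, 3))  # (B, h, T, dh)

    Q = split(x_q, params[prefix + "_Wq"], params[prefix + "_bq"])
    K = split(x_kv, params[prefix + "_Wk"], params[prefix + "_bk"])
    V = split(x_kv, params[prefix + "_Wv"], params[prefix + "_bv"])
    mask = None if mask_kv is None else anp.expand_dims(mask_kv, 1)  # (B,1,Tk)
    out, weights = scaled_dot_attention(Q, K, V, mask=mask)
    if collect is not None:
        collect.append(np.asarray(weights))
    if dropout > 0.0 and rng is not None:
        keep = rng.random(out.shape) >= dropout
        out = out * keep / (1.0 - dropout)
    out = anp.reshape(anp.transpose(out, (0, 2, 1, 3)), (B, Tq, H))
    return anp.matmul(out, params[prefix + "_Wo"]) + params[prefix + "_bo"]


def conv1d_k3(x, W, b):
    """Position-wise 1-D convolution, kernel 3, zero padding, stride 1.

    ``x`` (B, T, Cin), ``W`` (3, Cin, Cout).  y[t] = sum_k W[k] . x[t+k-1].
    """
    B, T, _C = x.shape
    zero = x[:, :1, :] * 0.0  # dtype-preserving zero column
    xm = anp.concatenate([zero, x, zero], axis=1)
    y = (
        anp.matmul(xm[:, :-2, :], W[0])
        + anp.matmul(xm[:, 1:-1, :], W[1])
        + anp.matmul(xm[:, 2:, :], W[2])
    )
    return y + b


def conv_feed_forward(x, params, prefix, mask=None, dropout=0.0, rng=None):
    """The block's feed-forward: two kernel-3 convolutions with a GELU between
    (the convolutional stand-in for the transformer's fully connected pair).

    The intermediate activation is re-masked: the stack's receptive field is
    5 positions, so without it a padded position would relay information from
    one valid neighbor to another and break padding invariance."""
    h = gelu(conv1d_k3(x, params[prefix + "_W1"], params[prefix + "_b1"]))
    if mask is not None:
        h = h * mask[:, :, None]
    h = conv1d_k3(h, params[prefix + "_W2"], params[prefix + "_b2"])
    if dropout > 0.0 and rng is not None:
        keep = rng.random(h.shape) >= dropout
        h = h * keep / (1.0 - dropout)
    return h


def clip_grad_norm(grads: dict, max_norm: float) -> dict:
    total = math.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
    if total > max_norm and total > 0:
        scale = max_norm / total
        return {k: g * scale for k, g in grads.items()}
    return grads
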