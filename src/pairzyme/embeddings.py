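"""Feature extraction: CBOW residue embeddings and reaction-pair encoding.

Enzyme sequences are embedded residue-by-residue with a continuous
bag-of-words (CBOW) model over the 21-letter alphabet (20 amino acids plus
the catch-all X): the center residue is predicted from its two flanking
residues through a V x N input matrix W and an N x V output matrix U with a
full-softmax likelihood,

    h = (1/C) W^T x,   y = U^T h,   p(w_O | w_I) = softmax(y)_{w_O},

with C = 2 context residues and N = 100 embedding dimensions.  The trained
row of W is the per-residue feature, giving an L x 100 matrix per enzyme.

Substrate-product pairs are encoded by a *frozen* reaction encoder (any
object satisfying :class:`ReactionEncoderInterface`) followed by a trainable
adapter head — two kernel-3 convolutions and a position-wise linear map —
that projects the frozen T x D token matrix to the model's T x H hidden
space.  A deterministic, seeded self-attention encoder over reaction-SMILES
characters is shipped so that no pretrained weights need downloading; a
pretrained encoder can be dropped in behind the same interface.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import autograd.numpy as anp
import numpy as np

from .nn import conv1d_k3, gelu, softmax

logger = logging.getLogger(__name__)

AA_TOKENS = tuple("ACDEFGHIKLMNPQRSTVWY") + ("X",)
VOCAB_SIZE = 21


@dataclass
class EmbeddingTable:
    """CBOW weights: vocab (size 21), input matrix W (V x N), output U (N x V)."""

    vocab: dict
    W: np.ndarray
    U: np.ndarray
    loss_history: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.vocab) != VOCAB_SIZE:
            raise ValueError(f"vocab must have {VOCAB_SIZE} tokens")
        if self.W.shape[0] != VOCAB_SIZE or self.U.shape[1] != VOCAB_SIZE:
            raise ValueError("W must be V x N and U must be N x V")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("non-finite embedding weights")

    @property
    def dim(self) -> int:
        return self.W.shape[1]

    def token_index(self, token: str) -> int:
        idx = self.vocab.get(token)
        if idx is None:
            logger.warning("unknown token %r mapped to X", token)
            idx = self.vocab["X"]
        return idx

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savez(out_dir / "cbow_weights.npz", W=self.W, U=self.U)
        (out_dir / "cbow_vocab.json").write_text(json.dumps(self.vocab))

    @classmethod
    def load(cls, out_dir) -> "EmbeddingTable":
        out_dir = Path(out_dir)
        data = np.load(out_dir / "cbow_weights.npz")
        vocab = json.loads((out_dir / "cbow_vocab.json").read_text())
        return cls(vocab=vocab, W=data["W"], U=data["U"])


@dataclass(frozen=True)
class EnzymeFeature:
    matrix: np.ndarray  # L x N
    enzyme_id: str


@dataclass(frozen=True)
class PairFeature:
    matrix: np.ndarray  # T x H
    pair_key: str


def default_vocab() -> dict:
    return {t: i for i, t in enumerate(AA_TOKENS)}


def _windows(sequences: Sequence[str], vocab: dict) -> tuple[np.ndarray, np.ndarray]:
    ctx, center = [], []
    for seq in sequences:
        idx = [vocab.get(c, vocab["X"]) for c in seq]
        for i in range(1, len(idx) - 1):
            ctx.append((idx[i - 1], idx[i + 1]))
            center.append(idx[i])
    if not ctx:
        raise ValueError("corpus contains no window of length 3")
    return np.asarray(ctx), np.asarray(center)


def train_cbow(
    sequences: Sequence[str],
    dim: int = 100,
    context: int = 2,
    epochs: int = 5,
    seed: int = 0,
    lr: float = 0.05,
    batch_size: int = 512,
) -> EmbeddingTable:
    """Fit the full-softmax CBOW objective on 3-residue windows.

    Each window predicts its center residue from ``context`` = 2 flanking
    residues.  With V = 21 the full softmax is cheap, so no negative
    sampling is used.  Reproducible under ``seed``.
    """
    vocab = default_vocab()
    ctx, center = _windows(sequences, vocab)
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, 0.1, size=(VOCAB_SIZE, dim))
    U = rng.normal(0.0, 0.1, size=(dim, VOCAB_SIZE))
    n = len(center)
    losses = []
    for _epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            sel = order[start : start + batch_size]
            c = ctx[sel]  # (B, context)
            t = center[sel]  # (B,)
            h = W[c].mean(axis=1)  # (B, dim); h = (1/C) W^T x
            y = h @ U  # (B, V)
            p = softmax(y, axis=-1)
            total += float(-np.log(np.maximum(p[np.arange(len(t)), t], 1e-12)).sum())
            err = p.copy()
            err[np.arange(len(t)), t] -= 1.0  # dL/dy
            dU = h.T @ err / len(t)
            # each context row sees dL/dh scaled by 1/C through the mean in h
            dh = err @ U.T / context
            U -= lr * dU
            np.add.at(W, c[:, 0], -lr * dh / len(t))
            np.add.at(W, c[:, 1], -lr * dh / len(t))
        losses.append(total / n)
    table = EmbeddingTable(vocab=vocab, W=W, U=U)
    table.loss_history = losses
    return table


def cbow_forward(table: EmbeddingTable, context_tokens: Sequence[str]) -> np.ndarray:
    """Probability over the 21 tokens of the center residue given context."""
    rows = [table.W[table.token_index(t)] for t in context_tokens]
    h = np.mean(rows, axis=0)
    y = h @ table.U
    return softmax(y, axis=-1)


def embed_enzyme(sequence: str, table: EmbeddingTable) -> EnzymeFeature:
    """Pure per-residue lookup into W; unknown residues use the X row."""
    if not sequence:
        raise ValueError("empty sequence")
    vocab = table.vocab
    x_idx = vocab["X"]
    idx = [vocab.get(c, x_idx) for c in sequence]
    return EnzymeFeature(matrix=table.W[idx], enzyme_id="")


# ---------------------------------------------------------------------------
# reaction-pair encoding


class ReactionEncoderInterface:
    """Contract: map a reaction SMILES ``A>>C`` to a frozen T x D matrix.

    Implementations must be deterministic, and their parameters are never
    touched by the trainer (verified by :meth:`params_hash`).
    """

    dim: int

    def encode(self, reaction_smiles: str) -> np.ndarray:
        raise NotImplementedError

    def params_hash(self) -> str:
        raise NotImplementedError


_SMILES_CHARS = list("CNOSPFIBclnosp[]()=#+-.0123456789@/\\>Hratseigu%*")


class FallbackReactionEncoder(ReactionEncoderInterface):
    """Frozen, seeded character-level self-attention reaction encoder.

    A small randomly-initialized embedding + 2-layer single-head
    self-attention network over the characters of ``A>>C``; fixed weights
    drawn once from ``seed``.  It provides deterministic, structure-sensitive
    token features without any pretrained download; a pretrained encoder can
    replace it behind :class:`ReactionEncoderInterface`.
    """

    def __init__(self, dim: int = 64, n_layers: int = 2, seed: int = 7):
        self.dim = dim
        self.n_layers = n_layers
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.char_vocab = {c: i for i, c in enumerate(_SMILES_CHARS)}
        V = len(self.char_vocab) + 1  # +1 catch-all bucket
        s = 1.0 / np.sqrt(dim)
        self.emb = rng.normal(0, 1.0, size=(V, dim))
        self.layers = []
        for _ in range(n_layers):
            self.layers.append(
                {
                    "Wq": rng.normal(0, s, size=(dim, dim)),
                    "Wk": rng.normal(0, s, size=(dim, dim)),
                    "Wv": rng.normal(0, s, size=(dim, dim)),
                    "Wf": rng.normal(0, s, size=(dim, dim)),
                }
            )

    def encode(self, reaction_smiles: str) -> np.ndarray:
        if not reaction_smiles or ">>" not in reaction_smiles:
            raise ValueError(f"not a reaction SMILES: {reaction_smiles!r}")
        idx = [
            self.char_vocab.get(c, len(self.char_vocab)) for c in reaction_smiles
        ]
        x = self.emb[idx]  # (T, D)
        for layer in self.layers:
            q, k, v = x @ layer["Wq"], x @ layer["Wk"], x @ layer["Wv"]
            scores = q @ k.T / np.sqrt(self.dim)
            w = softmax(scores, axis=-1)
            x = x + w @ v
            x = x + np.tanh(x @ layer["Wf"])
        # standardize token features so downstream magnitudes are stable
        x = (x - x.mean(axis=0, keepdims=True)) / (x.std(axis=0, keepdims=True) + 1e-6)
        return x

    def params_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.emb.tobytes())
        for layer in self.layers:
            for key in sorted(layer):
                h.update(layer[key].tobytes())
        return h.hexdigest()


def init_adapter_head(d_in: int, d_out: int, seed: int = 0) -> dict:
    """Trainable adapter: residual conv block then linear projection.

    out = (base + conv2(gelu(conv1(base)))) @ Wl + bl.  conv2 starts at zero
    (the residual branch is initially silent) and Wl starts at (truncated)
    identity, so with d_in == d_out the freshly initialized head is exactly
    the identity map.
    """
    rng = np.random.default_rng(seed)
    s = 1.0 / np.sqrt(3 * d_in)
    params = {
        "adapter_W1": rng.normal(0, s, size=(3, d_in, d_in)),
        "adapter_b1": np.zeros(d_in),
        "adapter_W2": np.zeros((3, d_in, d_in)),
        "adapter_b2": np.zeros(d_in),
        "adapter_Wl": np.eye(d_in, d_out),
        "adapter_bl": np.zeros(d_out),
    }
    return params


def apply_adapter(base, params, prefix: str = "adapter", mask=None):
    """Differentiable adapter application; ``base`` is (B, T, D) or (T, D).

    ``mask`` (B, T) re-masks the intermediate activation so padded tokens
    cannot relay information between valid neighbours through the two
    kernel-3 convolutions."""
    single = base.ndim == 2
    if single:
        base = base[None, :, :]
    h = gelu(conv1d_k3(base, params[prefix + "_W1"], params[prefix + "_b1"]))
    if mask is not None:
        h = h * mask[:, :, None]
    h = conv1d_k3(h, params[prefix + "_W2"], params[prefix + "_b2"])
    out = anp.matmul(base + h, params[prefix + "_Wl"]) + params[prefix + "_bl"]
    return out[0] if single else out


def embed_pair(
    pair,
    encoder: ReactionEncoderInterface,
    head: Optional[dict] = None,
    hidden: int = 64,
) -> PairFeature:
    """Encode a substrate-product pair to a T x H feature matrix.

    The frozen encoder produces the T x D base matrix; the (trainable)
    adapter head maps it to the model's hidden width H.
    """
    from .chem import pair_to_reaction_smiles

    key = pair_to_reaction_smiles(pair)
    base = encoder.encode(key)
    if head is None:
        head = init_adapter_head(encoder.dim, hidden)
    out = apply_adapter(base, head)
    return PairFeature(matrix=np.asarray(out), pair_key=key)
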