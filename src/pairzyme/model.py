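"""The promiscuity transformer: encoder over the enzyme, decoder over the pair.

The architecture is a transformer encoder-decoder with two deliberate
departures from the standard design: there is *no positional encoding*
anywhere (residue order enters only through the kernel-3 convolutional
feed-forwards), and every position-wise fully connected pair is replaced by
two 1-D convolutions.  The encoder self-attends over the L x 100 per-residue
enzyme features (projected to hidden width H); the decoder first self-attends
over the T x H substrate-product pair features and then cross-attends to the
encoder output — the cross-attention weights are the residue-importance
signal surfaced by :func:`attention_map`.  A mean-pool over decoder positions
feeds a fully connected 2-way softmax whose positive-class probability is the
catalysis score.

Residual-block weights use fixup initialization (first layer of a block
scaled by sqrt(2), last by sqrt(0.5), each divided by sqrt(fan-in)) while
layer normalization (norm shape = H) is retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import autograd.numpy as anp
import numpy as np

from . import nn
from .embeddings import (
    EmbeddingTable,
    FallbackReactionEncoder,
    ReactionEncoderInterface,
    apply_adapter,
    embed_enzyme,
    init_adapter_head,
)
from .nn import batched_mha, conv_feed_forward, fixup_init, layer_norm, softmax

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    n_layers: int = 12
    n_heads: int = 8
    hidden: int = 64
    norm_shape: int = 64
    dropout: float = 0.1
    max_enzyme_len: int = 1000
    enzyme_dim: int = 100

    def __post_init__(self):
        if self.hidden % self.n_heads:
            raise ValueError("hidden must be divisible by n_heads")
        if self.norm_shape != self.hidden:
            raise ValueError("norm shape must equal the hidden width")

    @classmethod
    def small(cls) -> "ModelConfig":
        """Desk-scale instance: 2+2 layers, 2 heads, H = 32."""
        return cls(n_layers=2, n_heads=2, hidden=32, norm_shape=32)


FORBIDDEN_PARAM_WORDS = ("pos", "positional")


def init_params(
    cfg: ModelConfig, encoder_dim: int, seed: int = 0
) -> dict:
    """Initialize all trainable tensors (fixup for residual-block weights)."""
    H = cfg.hidden
    params: dict[str, np.ndarray] = {}
    ss = np.random.SeedSequence(seed)

    def next_seed() -> int:
        return int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))

    rng = np.random.default_rng(next_seed())
    # input projection for the 100-dim residue features
    params["enz_in_W"] = rng.normal(0, 1.0 / np.sqrt(cfg.enzyme_dim),
                                    size=(cfg.enzyme_dim, H))
    params["enz_in_b"] = np.zeros(H)
    # adapter head projecting the frozen reaction-encoder output to H
    params.update(init_adapter_head(encoder_dim, H, seed=next_seed()))

    def mha_block(prefix: str):
        # attention residual block: QKV projections first, output proj last
        for name in ("Wq", "Wk", "Wv"):
            params[f"{prefix}_{name}"] = fixup_init(
                (H, H), 1, 2, H, seed=next_seed()
            )
            params[f"{prefix}_b{name[-1].lower()}"] = np.zeros(H)
        params[f"{prefix}_Wo"] = fixup_init((H, H), 2, 2, H, seed=next_seed())
        params[f"{prefix}_bo"] = np.zeros(H)

    def ff_block(prefix: str):
        params[f"{prefix}_W1"] = fixup_init((3, H, H), 1, 2, 3 * H,
                                            seed=next_seed())
        params[f"{prefix}_b1"] = np.zeros(H)
        params[f"{prefix}_W2"] = fixup_init((3, H, H), 2, 2, 3 * H,
                                            seed=next_seed())
        params[f"{prefix}_b2"] = np.zeros(H)

    def norms(prefix: str, n: int):
        for i in range(n):
            params[f"{prefix}_ln{i}_g"] = np.ones(H)
            params[f"{prefix}_ln{i}_b"] = np.zeros(H)

    for layer in range(cfg.n_layers):
        mha_block(f"enc{layer}_self")
        ff_block(f"enc{layer}_ff")
        norms(f"enc{layer}", 2)
        mha_block(f"dec{layer}_self")
        mha_block(f"dec{layer}_cross")
        ff_block(f"dec{layer}_ff")
        norms(f"dec{layer}", 3)
    params["final_ln_g"] = np.ones(H)
    params["final_ln_b"] = np.zeros(H)
    rng2 = np.random.default_rng(next_seed())
    params["head_W"] = rng2.normal(0, 1.0 / np.sqrt(H), size=(H, 2))
    params["head_b"] = np.zeros(2)
    for name in params:
        low = name.lower()
        assert not any(w in low for w in FORBIDDEN_PARAM_WORDS)
    # float32 throughout the trainable path keeps the autograd tape compact
    return {k: v.astype(np.float32) for k, v in params.items()}


def _ln(params, prefix: str, i: int, x, mask):
    out = layer_norm(x, params[f"{prefix}_ln{i}_g"], params[f"{prefix}_ln{i}_b"])
    return out * mask[:, :, None]


def forward(
    params: dict,
    cfg: ModelConfig,
    pair_base,
    pair_mask,
    enz_feat,
    enz_mask,
    train: bool = False,
    rng: Optional[np.random.Generator] = None,
    collect_attention: Optional[dict] = None,
):
    """Batched forward pass; returns positive-class probabilities (B,).

    ``pair_base`` (B, T, D) is the frozen reaction-encoder output (the
    trainable adapter is applied here so it participates in the gradient);
    ``enz_feat`` (B, L, 100) the CBOW residue features; masks are 1/0 floats.
    In evaluation mode (``train=False``) the pass is deterministic.
    """
    dropout = cfg.dropout if train else 0.0
    if train and dropout > 0 and rng is None:
        raise ValueError("training-mode forward needs an rng for dropout")
    mask_e = enz_mask[:, :, None]
    mask_p = pair_mask[:, :, None]

    x = anp.matmul(enz_feat, params["enz_in_W"]) + params["enz_in_b"]
    x = x * mask_e
    for layer in range(cfg.n_layers):
        pre = f"enc{layer}"
        coll = None
        if collect_attention is not None:
            coll = collect_attention.setdefault("encoder_self", [])
        h = batched_mha(
            _ln(params, pre, 0, x, enz_mask), _ln(params, pre, 0, x, enz_mask),
            params, f"{pre}_self", cfg.n_heads, mask_kv=enz_mask,
            dropout=dropout, rng=rng, collect=coll,
        )
        x = (x + h) * mask_e
        h = conv_feed_forward(
            _ln(params, pre, 1, x, enz_mask), params, f"{pre}_ff",
            mask=enz_mask, dropout=dropout, rng=rng,
        )
        x = (x + h) * mask_e
    enc_out = x

    y = apply_adapter(pair_base, params, mask=pair_mask)
    y = y * mask_p
    for layer in range(cfg.n_layers):
        pre = f"dec{layer}"
        coll_s = coll_c = None
        if collect_attention is not None:
            coll_s = collect_attention.setdefault("decoder_self", [])
            coll_c = collect_attention.setdefault("cross", [])
        h = batched_mha(
            _ln(params, pre, 0, y, pair_mask), _ln(params, pre, 0, y, pair_mask),
            params, f"{pre}_self", cfg.n_heads, mask_kv=pair_mask,
            dropout=dropout, rng=rng, collect=coll_s,
        )
        y = (y + h) * mask_p
        h = batched_mha(
            _ln(params, pre, 1, y, pair_mask), enc_out,
            params, f"{pre}_cross", cfg.n_heads, mask_kv=enz_mask,
            dropout=dropout, rng=rng, collect=coll_c,
        )
        y = (y + h) * mask_p
        h = conv_feed_forward(
            _ln(params, pre, 2, y, pair_mask), params, f"{pre}_ff",
            mask=pair_mask, dropout=dropout, rng=rng,
        )
        y = (y + h) * mask_p

    y = layer_norm(y, params["final_ln_g"], params["final_ln_b"]) * mask_p
    denom = anp.sum(pair_mask, axis=1, keepdims=True)
    pooled = anp.sum(y, axis=1) / anp.maximum(denom, 1.0)
    logits = anp.dot(pooled, params["head_W"]) + params["head_b"]
    probs = softmax(logits, axis=-1)
    return probs[:, 1]


@dataclass
class AttentionMap:
    """All attention weights of one forward pass plus residue importance.

    ``encoder_self[l][h]`` is L x L, ``decoder_self[l][h]`` T x T,
    ``cross[l][h]`` T x L; ``residue_importance`` (length L) is the cross
    weight averaged over layers, heads and pair positions — padded residues
    receive exactly zero.
    """

    encoder_self: list
    decoder_self: list
    cross: list
    residue_importance: np.ndarray


def attention_map(
    params: dict,
    cfg: ModelConfig,
    pair_base: np.ndarray,
    enz_feat: np.ndarray,
) -> AttentionMap:
    """Run one (unbatched) evaluation forward and collect attention weights."""
    L = enz_feat.shape[0]
    T = pair_base.shape[0]
    coll: dict = {}
    forward(
        params, cfg,
        pair_base[None], np.ones((1, T)),
        enz_feat[None], np.ones((1, L)),
        train=False, collect_attention=coll,
    )
    enc = [w[0] for w in coll["encoder_self"]]  # each (heads, L, L)
    dec = [w[0] for w in coll["decoder_self"]]
    cross = [w[0] for w in coll["cross"]]
    stacked = np.stack(cross)  # (layers, heads, T, L)
    importance = stacked.mean(axis=(0, 1, 2))
    return AttentionMap(
        encoder_self=[[head for head in layer] for layer in enc],
        decoder_self=[[head for head in layer] for layer in dec],
        cross=[[head for head in layer] for layer in cross],
        residue_importance=importance,
    )


class PromiscuityNet:
    """Bundle of trained parameters, CBOW table and frozen reaction encoder.

    Provides featurization and deterministic scoring of triads; the trainer
    mutates only ``params`` (the frozen encoder is hash-checked in tests).
    """

    def __init__(
        self,
        cfg: ModelConfig,
        table: EmbeddingTable,
        encoder: Optional[ReactionEncoderInterface] = None,
        params: Optional[dict] = None,
        seed: int = 0,
    ):
        self.cfg = cfg
        self.table = table
        self.encoder = encoder or FallbackReactionEncoder(dim=64)
        self.params = (
            params
            if params is not None
            else init_params(cfg, self.encoder.dim, seed=seed)
        )
        self._pair_cache: dict[str, np.ndarray] = {}
        self._enz_cache: dict[str, np.ndarray] = {}

    # -- featurization ----------------------------------------------------

    def pair_base(self, pair) -> np.ndarray:
        from .chem import pair_to_reaction_smiles

        key = pair_to_reaction_smiles(pair)
        if key not in self._pair_cache:
            self._pair_cache[key] = self.encoder.encode(key)
        return self._pair_cache[key]

    def enzyme_features(self, enzyme) -> np.ndarray:
        if enzyme.length > self.cfg.max_enzyme_len:
            raise ValueError(
                f"enzyme {enzyme.enzyme_id} has {enzyme.length} residues > "
                f"max {self.cfg.max_enzyme_len}; truncate or raise "
                f"max_enzyme_len explicitly"
            )
        if enzyme.sequence not in self._enz_cache:
            self._enz_cache[enzyme.sequence] = embed_enzyme(
                enzyme.sequence, self.table
            ).matrix
        return self._enz_cache[enzyme.sequence]

    def featurize(self, triads: Sequence) -> tuple:
        """Pad a batch of triads to common T and L; returns arrays + masks."""
        bases = [self.pair_base(t.pair) for t in triads]
        feats = [self.enzyme_features(t.enzyme) for t in triads]
        T = max(b.shape[0] for b in bases)
        L = max(f.shape[0] for f in feats)
        B = len(triads)
        D = bases[0].shape[1]
        E = feats[0].shape[1]
        pair_base = np.zeros((B, T, D), dtype=np.float32)
        pair_mask = np.zeros((B, T), dtype=np.float32)
        enz_feat = np.zeros((B, L, E), dtype=np.float32)
        enz_mask = np.zeros((B, L), dtype=np.float32)
        for i, (b, f) in enumerate(zip(bases, feats)):
            pair_base[i, : b.shape[0]] = b
            pair_mask[i, : b.shape[0]] = 1.0
            enz_feat[i, : f.shape[0]] = f
            enz_mask[i, : f.shape[0]] = 1.0
        return pair_base, pair_mask, enz_feat, enz_mask

    # -- inference --------------------------------------------------------

    def score(self, triads: Sequence, batch_size: int = 32) -> np.ndarray:
        """Deterministic catalysis probabilities for a list of triads."""
        out = np.empty(len(triads))
        # batch by enzyme length so padding (and the L^2 attention cost)
        # stays small; scores are padding-invariant so order is free
        order = np.argsort([t.enzyme.length for t in triads], kind="stable")
        for start in range(0, len(order), batch_size):
            sel = order[start : start + batch_size]
            batch = [triads[i] for i in sel]
            pb, pm, ef, em = self.featurize(batch)
            out[sel] = np.asarray(
                forward(self.params, self.cfg, pb, pm, ef, em, train=False)
            )
        return out

    def attention_for(self, triad) -> AttentionMap:
        return attention_map(
            self.params,
            self.cfg,
            self.pair_base(triad.pair),
            self.enzyme_features(triad.enzyme),
        )

    # -- persistence ------------------------------------------------------

    CHECKPOINT_VERSION = 1

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savez(out_dir / "weights.npz", **self.params)
        (out_dir / "model.json").write_text(
            json.dumps(
                {
                    "version": self.CHECKPOINT_VERSION,
                    "config": asdict(self.cfg),
                    "encoder": {
                        "kind": "fallback",
                        "dim": self.encoder.dim,
                        "seed": getattr(self.encoder, "seed", None),
                    },
                },
                indent=2,
            )
        )
        self.table.save(out_dir)

    @classmethod
    def load(cls, out_dir) -> "PromiscuityNet":
        out_dir = Path(out_dir)
        meta = json.loads((out_dir / "model.json").read_text())
        if meta["version"] != cls.CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg = ModelConfig(**meta["config"])
        data = np.load(out_dir / "weights.npz")
        params = {k: data[k] for k in data.files}
        table = EmbeddingTable.load(out_dir)
        enc = FallbackReactionEncoder(
            dim=meta["encoder"]["dim"], seed=meta["encoder"]["seed"] or 7
        )
        return cls(cfg=cfg, table=table, encoder=enc, params=params)
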