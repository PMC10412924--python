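"""Multi-scale tokenization, attention-threshold masking and fusion.

Each input stream (a student-encoder feature map, optionally the raw apex
frame) is split into ``s x s`` non-overlapping patches, projected to a
``q``-dimensional embedding, given positional embeddings and a learnable
class token, and passed through ``L`` pre-norm MSA+MLP transformer blocks.

The class token's attention row over the patch keys in the *final* block
(averaged over heads, renormalized to sum 1) serves as the per-patch
attention weight vector.  Patches whose weight falls below the threshold
``theta`` are masked — dropped from pooling entirely, not zero-filled — so
that only regions the model deems expression-relevant reach the fusion
classifier.  Ties at exactly ``theta`` count as retained.  If no patch
clears the threshold, the single highest-weight patch (lowest index on
ties) is kept so the fused representation is never empty.

Fusion mean-pools each stream's surviving tokens (class token included),
averages the per-stream vectors with equal weight, and classifies through a
small MLP; every stream additionally gets its own linear classification
head for the per-scale loss terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, softmax
from .nn import DTYPE, LayerNorm, Linear, Module, TransformerBlock

__all__ = [
    "TokenizerConfig",
    "EncoderConfig",
    "TokenSequence",
    "ScaleOutput",
    "FusionOutput",
    "ScaleTokenizer",
    "TransformerEncoder",
    "FusionHead",
    "patchify_and_embed",
    "encode",
    "mask_tokens",
    "fuse_classify",
]


@dataclass(frozen=True)
class TokenizerConfig:
    """Patch-grid geometry and embedding width of one stream."""

    s: int = 4  # patches per image side -> k = s*s tokens
    q: int = 64  # embedding dimension

    def __post_init__(self):
        if self.s < 2:
            raise ValueError(f"s must be >= 2, got {self.s}")
        if self.q <= 0:
            raise ValueError(f"q must be positive, got {self.q}")

    @property
    def k(self) -> int:
        return self.s * self.s


@dataclass(frozen=True)
class EncoderConfig:
    L: int = 4
    heads: int = 4
    mlp_hidden: int = 128
    theta: float | None = None  # None -> 0.8/k (just below the uniform weight 1/k)
    attention_readout: str = "rollout"  # "rollout" | "final" block | "mean" over blocks

    def __post_init__(self):
        if self.L < 1 or self.heads < 1:
            raise ValueError("L and heads must be >= 1")
        if self.theta is not None and not 0.0 <= self.theta < 1.0:
            raise ValueError(f"theta must lie in [0, 1), got {self.theta}")
        if self.attention_readout not in ("rollout", "final", "mean"):
            raise ValueError(
                f"attention_readout must be 'rollout', 'final' or 'mean', got {self.attention_readout}"
            )

    def resolve_theta(self, k: int) -> float:
        # below 1/k: flat attention then cannot zero the mask loss, so the
        # mask term rewards concentration instead of uniformity
        return 0.8 / k if self.theta is None else self.theta


@dataclass
class TokenSequence:
    """(B, k+1, q) token matrix; row 0 is the class token."""

    tokens: Tensor
    scale_index: int

    @property
    def k(self) -> int:
        return self.tokens.shape[1] - 1


@dataclass
class ScaleOutput:
    """Encoded stream plus its class-attention readout and retained set."""

    encoded: Tensor  # (B, k+1, q)
    patch_weights: np.ndarray  # (B, k), rows sum to 1
    retained: list[np.ndarray]  # per-sample sorted patch indices (0-based)
    scale_index: int
    theta: float | None = None
    weights_t: Tensor | None = None  # differentiable view of patch_weights

    @property
    def k(self) -> int:
        return self.patch_weights.shape[1]


@dataclass
class FusionOutput:
    p: Tensor  # (B, n_classes) fused probabilities
    p_scale: list[Tensor]  # per-stream probability matrices

    def predictions(self) -> np.ndarray:
        return np.argmax(self.p.data, axis=1)


class ScaleTokenizer(Module):
    """Patch projection + positional table + class token for one stream."""

    def __init__(self, channels: int, spatial: int, config: TokenizerConfig, rng: np.random.Generator):
        if spatial % config.s:
            raise ValueError(f"spatial size {spatial} not divisible by s={config.s}")
        self.config = config
        self.channels = channels
        self.spatial = spatial
        self.patch = spatial // config.s
        self.proj = Linear(channels * self.patch**2, config.q, rng)
        self.pos = Tensor(rng.normal(0, 0.02, size=(config.k, config.q)).astype(DTYPE), requires_grad=True)
        self.cls = Tensor(rng.normal(0, 0.02, size=(1, config.q)).astype(DTYPE), requires_grad=True)


def _to_nchw(feature_map) -> Tensor:
    if isinstance(feature_map, Tensor):
        t = feature_map
    else:
        t = Tensor(np.asarray(feature_map, dtype=DTYPE))
    if t.ndim == 2:  # H,W
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 3:  # C,H,W
        t = t.reshape(1, *t.shape)
    return t


def patchify_and_embed(feature_map, tokenizer: ScaleTokenizer, scale_index: int = 1) -> TokenSequence:
    """Split into s x s patches, project to q dims, add positions + class token."""
    x = _to_nchw(feature_map)
    b, c, h, w = x.shape
    s = tokenizer.config.s
    if h % s or w % s:
        raise ValueError(f"feature map {h}x{w} not divisible into {s}x{s} patches")
    if c != tokenizer.channels:
        raise ValueError(f"feature map has {c} channels, tokenizer expects {tokenizer.channels}")
    p = h // s
    k, q = tokenizer.config.k, tokenizer.config.q
    # (B,C,s,p,s,p) -> (B,s,s,C,p,p) -> (B,k,C*p*p)
    patches = x.reshape(b, c, s, p, s, p).transpose(0, 2, 4, 1, 3, 5).reshape(b, k, c * p * p)
    emb = patches @ tokenizer.proj.weight + tokenizer.proj.bias  # (B,k,q)
    emb = emb + tokenizer.pos
    cls = Tensor(np.ones((b, 1, 1), dtype=DTYPE)) * tokenizer.cls.reshape(1, 1, q)
    return TokenSequence(tokens=concat([cls, emb], axis=1), scale_index=scale_index)


class TransformerEncoder(Module):
    """L pre-norm MSA+MLP blocks for one stream."""

    def __init__(self, dim: int, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        self.blocks = [TransformerBlock(dim, config.heads, config.mlp_hidden, rng) for _ in range(config.L)]
        self.norm = LayerNorm(dim)


def class_attention_weights(attn: Tensor) -> Tensor:
    """Class-token attention over patch keys, head-averaged and renormalized."""
    w = attn[:, :, 0, 1:].mean(axis=1)  # (B, k)
    return w / w.sum(axis=1, keepdims=True)


def encode(seq: TokenSequence, encoder: TransformerEncoder) -> ScaleOutput:
    """Run the block stack; read out patch weights; apply the theta mask."""
    x = seq.tokens
    attns = []
    for blk in encoder.blocks:
        x, attn = blk(x)
        attns.append(attn)
    x = encoder.norm(x)
    if not np.all(np.isfinite(x.data)):
        raise RuntimeError(f"non-finite activations after block {len(encoder.blocks)}")
    mode = encoder.config.attention_readout
    if mode == "final":
        weights = class_attention_weights(attns[-1])
    elif mode == "mean":
        per_block = [class_attention_weights(a) for a in attns]
        acc = per_block[0]
        for w in per_block[1:]:
            acc = acc + w
        weights = acc * (1.0 / len(per_block))
    else:  # attention rollout through the residual stream
        roll = None
        eye = None
        for a in attns:
            m = a.mean(axis=1)  # head-averaged (B, T, T)
            if eye is None:
                eye = Tensor(np.broadcast_to(np.eye(m.shape[-1], dtype=m.data.dtype), m.shape).copy())
            m = m * 0.5 + eye * 0.5  # account for the residual connection
            roll = m if roll is None else m @ roll
        w = roll[:, 0, 1:]
        weights = w / w.sum(axis=1, keepdims=True)
    out = ScaleOutput(
        encoded=x,
        patch_weights=weights.data,
        retained=[],
        scale_index=seq.scale_index,
        weights_t=weights,
    )
    theta = encoder.config.resolve_theta(out.k)
    return mask_tokens(out, theta)


def retained_indices(weights: np.ndarray, theta: float) -> np.ndarray:
    """{j : w_j >= theta}; argmax fallback (lowest index on ties) if empty."""
    keep = np.flatnonzero(weights >= theta)
    if keep.size == 0:
        keep = np.array([int(np.argmax(weights))])
    return keep


def mask_tokens(out: ScaleOutput, theta: float) -> ScaleOutput:
    """Recompute the retained set under ``theta`` (class token always kept)."""
    if not 0.0 <= theta < 1.0:
        raise ValueError(f"theta must lie in [0, 1), got {theta}")
    retained = [retained_indices(w, theta) for w in out.patch_weights]
    return ScaleOutput(
        encoded=out.encoded,
        patch_weights=out.patch_weights,
        retained=retained,
        scale_index=out.scale_index,
        theta=theta,
        weights_t=out.weights_t,
    )


class FusionHead(Module):
    """Per-stream linear heads + the fusion MLP over the averaged pooled vector."""

    def __init__(self, q: int, n_classes: int, n_streams: int, rng: np.random.Generator, hidden: int = 64):
        self.scale_heads = [Linear(q, n_classes, rng) for _ in range(n_streams)]
        self.fc1 = Linear(q, hidden, rng)
        self.fc2 = Linear(hidden, n_classes, rng)

    def fusion_mlp(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


def _pool_retained(out: ScaleOutput, pooling: str = "attention") -> Tensor:
    """Pool the class token with the retained patch tokens.

    ``"attention"`` (default): the retained patches are combined with their
    attention weights (renormalized over the retained set) and averaged
    with the class token.  This keeps a differentiable path from the
    classification losses into the attention weights, so the model is
    explicitly rewarded for attending to class-informative regions.

    ``"mean"``: plain mean over class token + retained patches; the
    attention weights then only influence classification through the
    discrete retained set.
    """
    b, t, q = out.encoded.shape
    keep = np.zeros((b, t - 1), dtype=out.encoded.data.dtype)
    for i, idx in enumerate(out.retained):
        keep[i, idx] = 1.0
    cls = out.encoded[:, 0]
    if pooling in ("attention", "attention_patches"):
        w = out.weights_t if out.weights_t is not None else Tensor(out.patch_weights)
        wk = w * Tensor(keep)
        wk = wk / wk.sum(axis=1, keepdims=True)
        patches = (out.encoded[:, 1:] * wk.reshape(b, t - 1, 1)).sum(axis=1)
        if pooling == "attention_patches":
            return patches
    elif pooling == "mean":
        counts = keep.sum(axis=1, keepdims=True)
        patches = (out.encoded[:, 1:] * Tensor(keep[:, :, None])).sum(axis=1) / Tensor(counts)
    else:
        raise ValueError(f"pooling must be 'attention', 'attention_patches' or 'mean', got {pooling!r}")
    return (cls + patches) * 0.5


def fuse_classify(
    scale_outputs: list[ScaleOutput], head: FusionHead, pooling: str = "attention"
) -> FusionOutput:
    """Equal-weight average of per-stream pooled vectors -> fusion MLP -> softmax."""
    if not scale_outputs:
        raise ValueError("fuse_classify needs at least one scale output")
    qdims = {o.encoded.shape[-1] for o in scale_outputs}
    if len(qdims) > 1:
        raise ValueError(f"embedding dims differ across scales: {sorted(qdims)}")
    pooled = [_pool_retained(o, pooling) for o in scale_outputs]
    fused = pooled[0]
    for v in pooled[1:]:
        fused = fused + v
    fused = fused * (1.0 / len(pooled))
    p = softmax(head.fusion_mlp(fused), axis=-1)
    p_scale = [softmax(h(v), axis=-1) for h, v in zip(head.scale_heads, pooled)]
    return FusionOutput(p=p, p_scale=p_scale)
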