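"""Neural-network layers built on :mod:`mfvan.autodiff`.

Layers hold their parameters as :class:`~mfvan.autodiff.Tensor` objects and
expose them through ``parameters()`` for the optimizer and for checkpoint
serialization.  All initialization draws from an explicitly passed
``numpy.random.Generator`` so every model is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv2d, softmax

DTYPE = np.float32


class Module:
    """Base class: recursively collects parameters from attributes."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, model expects {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype)


def _param(arr: np.ndarray) -> Tensor:
    return Tensor(np.asarray(arr, dtype=DTYPE), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.weight = _param(w)
        self.bias = _param(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """Strided/padded 2-D convolution (NCHW)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        zero_init: bool = False,
    ):
        fan_in = c_in * kernel * kernel
        if zero_init:
            w = np.zeros((c_out, c_in, kernel, kernel))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        self.weight = _param(w)
        self.bias = _param(np.zeros(c_out))
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2x2(Module):
    """2x upsampling transposed convolution (kernel 2, stride 2).

    With kernel = stride the output blocks do not overlap, so the op reduces
    to a per-pixel linear map into 2x2 output blocks — expressed here with
    reshape/matmul so no dedicated backward is needed.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.weight = _param(rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out * 4)))
        self.bias = _param(np.zeros(c_out))
        self.c_out = c_out

    def __call__(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        y = x.transpose(0, 2, 3, 1).reshape(b * h * w, c) @ self.weight  # (BHW, O*4)
        y = y.reshape(b, h, w, self.c_out, 2, 2)
        y = y.transpose(0, 3, 1, 4, 2, 5).reshape(b, self.c_out, 2 * h, 2 * w)
        return y + self.bias.reshape(1, self.c_out, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = _param(np.ones(dim))
        self.beta = _param(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Standard multi-head self-attention over a (B, T, q) sequence.

    ``__call__`` returns the output sequence together with the attention
    matrix (B, heads, T, T) so the class-token row can be read out.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"embedding dim {dim} not divisible by {heads} heads")
        self.heads = heads
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        b, t, q = x.shape
        h, d = self.heads, self.head_dim
        qkv = self.qkv(x).reshape(b, t, 3, h, d).transpose(2, 0, 3, 1, 4)  # 3,B,h,T,d
        qs, ks, vs = qkv[0], qkv[1], qkv[2]
        scores = (qs @ ks.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        attn = softmax(scores, axis=-1)  # B,h,T,T
        out = attn @ vs  # B,h,T,d
        out = out.transpose(0, 2, 1, 3).reshape(b, t, q)
        return self.proj(out), attn


class TransformerBlock(Module):
    """Pre-norm MSA + MLP residual block."""

    def __init__(self, dim: int, heads: int, mlp_hidden: int, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_hidden, rng)
        self.fc2 = Linear(mlp_hidden, dim, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        a, attn = self.attn(self.norm1(x))
        x = x + a
        x = x + self.fc2(self.fc1(self.norm2(x)).gelu())
        return x, attn


class Adam:
    """Adam optimizer with the standard bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def as_batch(images: np.ndarray) -> Tensor:
    """Stack (H,W) or (H,W,C) images into an NCHW float tensor."""
    arr = np.asarray(images, dtype=DTYPE)
    if arr.ndim == 3:  # B,H,W -> B,1,H,W
        arr = arr[:, None, :, :]
    elif arr.ndim == 4 and arr.shape[-1] in (1, 3):  # B,H,W,C -> B,C,H,W
        arr = arr.transpose(0, 3, 1, 2)
    return Tensor(arr)
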