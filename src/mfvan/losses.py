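"""Joint training objective: focal classification, mask and identity losses.

The full objective is a plain sum

    L_all = L_remove + L_class_global(p, y) + sum_i L_class_scale,i + L_mask

where ``L_remove`` is the identity-removal reconstruction loss, the
classification terms are focal losses on the fused prediction ``p`` and the
per-scale predictions, and ``L_mask`` sums the attention weights that
survive the ``theta`` threshold.  The focal loss

    L_class = -alpha_t (1 - p_t)^r log(p_t)

down-weights easy samples through the focusing exponent ``r`` and balances
classes through the per-class weights ``alpha_t``.  The mask loss penalizes
exactly the weights that are retained (``f_c >= theta``); weights already
below the threshold contribute zero.  Because each stream's weights sum to
one, it measures the attention mass the model keeps after masking.

Every function accepts plain arrays (returning floats, used in tests and
reporting) or autodiff tensors (returning tensors, used in training).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = ["LossConfig", "LossBreakdown", "focal_loss", "mask_loss", "joint_loss"]

_EPS = 1e-12  # probability clamp ahead of log


@dataclass(frozen=True)
class LossConfig:
    """Hyperparameters and component toggles of the joint objective."""

    alpha: tuple[float, ...] | None = None  # per-class weights; None -> all ones
    gamma: float = 2.0  # focusing exponent r
    theta: float | None = None  # attention threshold, shared with the encoder
    mask_scale: float = 1.0  # multiplier on L_mask (1 = objective as stated)
    use_remove: bool = True
    use_global: bool = True
    use_scale: bool = True
    use_mask: bool = True

    def __post_init__(self):
        if self.alpha is not None and any(a <= 0 for a in self.alpha):
            raise ValueError("alpha entries must be positive")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")

    def alpha_for(self, n_classes: int) -> np.ndarray:
        if self.alpha is None:
            return np.ones(n_classes)
        if len(self.alpha) != n_classes:
            raise ValueError(f"alpha has {len(self.alpha)} entries for {n_classes} classes")
        return np.asarray(self.alpha, dtype=float)


@dataclass
class LossBreakdown:
    """Named components of the joint objective; ``total`` is their exact sum."""

    L_remove: float
    L_class_global: float
    L_class_scale: tuple[float, float, float]
    L_mask: float
    L_all: float

    def as_dict(self) -> dict:
        d = {"L_remove": self.L_remove, "L_class_global": self.L_class_global}
        for i, v in enumerate(self.L_class_scale, start=1):
            d[f"L_scale{i}"] = v
        d.update(L_mask=self.L_mask, L_all=self.L_all)
        return d


def inverse_frequency_alpha(labels: list[str], classes: list[str]) -> tuple[float, ...]:
    """Per-class weights proportional to inverse frequency, normalized to mean 1."""
    counts = np.array([max(1, labels.count(c)) for c in classes], dtype=float)
    w = 1.0 / counts
    return tuple(w / w.mean())


def focal_loss(probs, true_class, config: LossConfig) -> float:
    """Focal loss ``-alpha_t (1-p_t)^r log(p_t)``.

    ``probs`` may be a single probability vector with an integer
    ``true_class``, or a (B, C) matrix with a length-B index sequence, in
    which case the per-sample losses are averaged.  Tensor input keeps the
    computation differentiable.
    """
    if isinstance(probs, Tensor):
        return _focal_tensor(probs, true_class, config)
    p = np.asarray(probs, dtype=float)
    t = np.asarray(true_class)
    if p.ndim == 1:
        p, t = p[None, :], np.atleast_1d(t)
    n, c = p.shape
    if np.any(t < 0) or np.any(t >= c):
        raise IndexError(f"true_class out of range for {c} classes")
    alpha = config.alpha_for(c)
    pt = np.clip(p[np.arange(n), t], _EPS, 1.0)
    losses = -alpha[t] * (1.0 - pt) ** config.gamma * np.log(pt)
    return float(losses.mean())


def _focal_tensor(probs: Tensor, true_class, config: LossConfig) -> Tensor:
    t = np.atleast_1d(np.asarray(true_class))
    n, c = probs.shape
    alpha = config.alpha_for(c)
    onehot = np.zeros((n, c), dtype=probs.data.dtype)
    onehot[np.arange(n), t] = 1.0
    pt = (probs * Tensor(onehot)).sum(axis=1).clamp_min(_EPS)
    w = Tensor(alpha[t].astype(probs.data.dtype))
    return (w * (1.0 - pt) ** config.gamma * -(pt.log())).mean()


def mask_loss(patch_weights, theta: float) -> float:
    """Attention mass surviving the threshold: sum of ``w_j`` where ``w_j >= theta``.

    ``patch_weights`` is one weight vector or a list of per-scale vectors
    (summed over scales).  Tensor input keeps gradients flowing into the
    retained weights (the branch indicator is treated as a constant).
    """
    if isinstance(patch_weights, (list, tuple)):
        total = None
        for w in patch_weights:
            term = mask_loss(w, theta)
            total = term if total is None else total + term
        return total
    if isinstance(patch_weights, Tensor):
        keep = (patch_weights.data >= theta).astype(patch_weights.data.dtype)
        per_sample = (patch_weights * Tensor(keep)).sum(axis=-1)
        return per_sample.mean() if per_sample.ndim else per_sample
    w = np.asarray(patch_weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("patch weights must be nonnegative")
    kept = w[w >= theta]
    if w.ndim == 1:
        return float(kept.sum())
    return float((w * (w >= theta)).sum(axis=-1).mean())


def joint_loss(
    l_remove,
    global_probs,
    scale_probs,
    patch_weights,
    true_class,
    config: LossConfig,
    theta: float,
) -> LossBreakdown:
    """Assemble the joint objective from its pieces (floats; reporting path).

    Disabled components are recorded as 0 and excluded; ``L_all`` is the
    exact sum of the enabled ones.
    """
    if len(scale_probs) != 3:
        raise ValueError(f"expected 3 per-scale probability sets, got {len(scale_probs)}")
    lr = float(l_remove) if config.use_remove else 0.0
    lg = focal_loss(global_probs, true_class, config) if config.use_global else 0.0
    if config.use_scale:
        ls = tuple(focal_loss(p, true_class, config) for p in scale_probs)
    else:
        ls = (0.0, 0.0, 0.0)
    lm = config.mask_scale * mask_loss(patch_weights, theta) if config.use_mask else 0.0
    total = lr + lg + sum(ls) + lm
    return LossBreakdown(L_remove=lr, L_class_global=lg, L_class_scale=ls, L_mask=lm, L_all=total)
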