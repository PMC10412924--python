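"""Identity-attribute removal by apex-to-onset distillation.

The onset frame of a micro-expression clip shows the subject in a neutral
state, so it can be read as a pure identity image; the apex frame couples
that identity with the expression.  Mapping apex to onset with an
autoencoder therefore strips the expression of identity-specific appearance
while the *encoder* of the mapping network retains the expression-relevant
change features — those encoder feature maps are what the downstream
multi-scale transformer consumes.

Training happens in two stages:

1. ``pretrain_teacher`` — a deeper residual conv autoencoder learns plain
   self-reconstruction on all frames (onset and apex), giving it a general
   face representation despite the small dataset (loss ``L_pre``).
2. ``distill_student`` — teacher and student are then jointly trained to
   map apex to onset; the teacher continues from its pretrained weights and
   acts as the soft target guiding the shallow student.  The objective is
   ``L_remove = L_teacher + L_student``, both plain per-pixel MSE against
   the onset frame.

The student decodes through skip connections plus a global residual path
from the apex input, with a zero-initialized output head: at initialization
the student reproduces the apex exactly, and training only has to learn the
*correction* toward the neutral frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import Adam, Conv2d, ConvTranspose2x2, Module, as_batch

__all__ = [
    "ImagePair",
    "DistillationConfig",
    "MultiScaleFeatureMaps",
    "TeacherNet",
    "StudentNet",
    "reconstruction_loss",
    "pretrain_teacher",
    "distill_student",
    "extract_multiscale",
]


@dataclass
class ImagePair:
    """Onset (neutral) and apex (peak-expression) frames of one sample."""

    onset: np.ndarray
    apex: np.ndarray

    def __post_init__(self):
        if self.onset.shape != self.apex.shape:
            raise ValueError(f"onset shape {self.onset.shape} != apex shape {self.apex.shape}")
        if self.onset.ndim not in (2, 3) or min(self.onset.shape[:2]) == 0:
            raise ValueError(f"expected H x W (x C) images, got shape {self.onset.shape}")


@dataclass(frozen=True)
class DistillationConfig:
    teacher_depth: int = 4
    student_depth: int = 3
    epochs: int = 30
    batch_size: int = 24
    learning_rate: float = 2e-3
    seed: int = 0
    scale_taps: tuple[int, ...] = (0, 1, 2)  # student encoder stages emitting feature maps
    freeze_teacher: bool = False  # freeze teacher weights during distillation (ablation)
    teacher_channels: tuple[int, ...] = (8, 16, 24, 32)
    student_channels: tuple[int, ...] = (8, 16, 24)

    def __post_init__(self):
        if self.student_depth >= self.teacher_depth:
            raise ValueError("student must be shallower than the teacher")
        if len(self.scale_taps) != 3:
            raise ValueError("exactly 3 scale taps are required")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class MultiScaleFeatureMaps:
    """Three encoder feature maps (spatial size halving per scale) + the apex frame."""

    maps: list[np.ndarray]  # each (C_i, H/2^{i+1}, W/2^{i+1})
    source: np.ndarray  # the apex frame itself, the "original scale" input

    def __post_init__(self):
        if len(self.maps) != 3:
            raise ValueError(f"expected 3 feature maps, got {len(self.maps)}")
        for a, b in zip(self.maps, self.maps[1:]):
            if not (b.shape[-1] < a.shape[-1] and b.shape[-2] < a.shape[-2]):
                raise ValueError("feature map spatial dims must strictly decrease with scale")


def reconstruction_loss(target, generated) -> float:
    """Per-pixel mean squared error ``(1/(N*M)) sum |t_ij - g_ij|^2``.

    Channels, when present, are averaged as well.  Accepts plain arrays
    (returns a float) or autodiff tensors (returns a Tensor for training).
    """
    if isinstance(target, Tensor) or isinstance(generated, Tensor):
        t = target if isinstance(target, Tensor) else Tensor(np.asarray(target))
        g = generated if isinstance(generated, Tensor) else Tensor(np.asarray(generated))
        if t.shape != g.shape:
            raise ValueError(f"shape mismatch: target {t.shape} vs generated {g.shape}")
        return ((t - g) ** 2).mean()
    t = np.asarray(target, dtype=np.float64)
    g = np.asarray(generated, dtype=np.float64)
    if t.shape != g.shape:
        raise ValueError(f"shape mismatch: target {t.shape} vs generated {g.shape}")
    return float(np.mean((t - g) ** 2))


class _ResDownBlock(Module):
    """Stride-2 downsampling conv followed by a residual 3x3 conv."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, residual: bool = True):
        self.down = Conv2d(c_in, c_out, kernel=3, rng=rng, stride=2, padding=1)
        self.res = Conv2d(c_out, c_out, kernel=3, rng=rng, stride=1, padding=1) if residual else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.down(x).relu()
        if self.res is not None:
            h = (h + self.res(h)).relu()
        return h


class TeacherNet(Module):
    """Deep residual conv autoencoder; decodes via transposed convolutions.

    Residual refinement convs are applied only from the second stage down,
    where the spatial grid is small enough for them to be cheap.
    """

    def __init__(self, config: DistillationConfig, rng: np.random.Generator, in_channels: int = 1):
        chans = config.teacher_channels[: config.teacher_depth]
        self.enc = []
        c_prev = in_channels
        for i, c in enumerate(chans):
            self.enc.append(_ResDownBlock(c_prev, c, rng, residual=i > 0))
            c_prev = c
        self.dec = []
        for c in reversed(chans[:-1]):
            self.dec.append(ConvTranspose2x2(c_prev, c, rng))
            c_prev = c
        self.dec.append(ConvTranspose2x2(c_prev, max(chans[0] // 2, 4), rng))
        self.head = Conv2d(max(chans[0] // 2, 4), in_channels, kernel=3, rng=rng, padding=1)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for blk in self.enc:
            h = blk(h)
        for up in self.dec:
            h = up(h).relu()
        return self.head(h)


class StudentNet(Module):
    """Shallow apex-to-onset mapping network with multi-scale encoder taps.

    Three stride-2 encoder stages produce the feature maps consumed by the
    tokenizer; the decoder mirrors them with 2x transposed convolutions and
    skip additions, and the zero-initialized head makes the network an exact
    identity map at initialization (output = apex + correction).
    """

    def __init__(self, config: DistillationConfig, rng: np.random.Generator, in_channels: int = 1):
        c1, c2, c3 = config.student_channels[: config.student_depth]
        self.conv1 = Conv2d(in_channels, c1, kernel=3, rng=rng, stride=2, padding=1)
        self.conv2 = Conv2d(c1, c2, kernel=3, rng=rng, stride=2, padding=1)
        self.conv3 = Conv2d(c2, c3, kernel=3, rng=rng, stride=2, padding=1)
        self.up3 = ConvTranspose2x2(c3, c2, rng)
        self.up2 = ConvTranspose2x2(c2, c1, rng)
        self.up1 = ConvTranspose2x2(c1, c1, rng)
        self.head = Conv2d(c1, in_channels, kernel=3, rng=rng, padding=1, zero_init=True)
        self.scale_taps = tuple(config.scale_taps)

    def encode(self, x: Tensor) -> list[Tensor]:
        e1 = self.conv1(x).relu()
        e2 = self.conv2(e1).relu()
        e3 = self.conv3(e2).relu()
        return [e1, e2, e3]

    def __call__(self, x: Tensor) -> Tensor:
        e1, e2, e3 = self.encode(x)
        d2 = (self.up3(e3) + e2).relu()
        d1 = (self.up2(d2) + e1).relu()
        d0 = self.up1(d1).relu()
        return x + self.head(d0)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _check_finite(value: float, epoch: int, name: str) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"{name} became non-finite at epoch {epoch}")


def pretrain_teacher(
    images: list[np.ndarray], config: DistillationConfig
) -> tuple[TeacherNet, list[float]]:
    """Self-supervised reconstruction pretraining (loss ``L_pre``).

    Returns the teacher and a loss trace whose entry 0 is the initial
    full-set loss; entry e >= 1 is the mean minibatch loss of epoch e.
    """
    if not images:
        raise ValueError("pretrain_teacher needs at least one image")
    shapes = {np.asarray(im).shape for im in images}
    if len(shapes) > 1:
        raise ValueError(f"all images must share one shape, got {sorted(shapes)}")

    rng = np.random.default_rng([config.seed, 101])
    in_ch = 1 if len(next(iter(shapes))) == 2 else next(iter(shapes))[-1]
    teacher = TeacherNet(config, rng, in_channels=in_ch)
    batch_all = as_batch(np.stack(images))
    trace = [reconstruction_loss(batch_all.data, teacher(batch_all).data)]

    opt = Adam(teacher.parameters(), lr=config.learning_rate)
    for epoch in range(1, config.epochs + 1):
        losses = []
        for idx in _batches(len(images), config.batch_size, rng):
            xb = Tensor(batch_all.data[idx])
            loss = reconstruction_loss(xb, teacher(xb))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)))
        _check_finite(trace[-1], epoch, "L_pre")
    return teacher, trace


def distill_student(
    pairs: list[ImagePair], teacher: TeacherNet, config: DistillationConfig
) -> tuple[StudentNet, list[dict]]:
    """Joint apex->onset training of teacher and student (``L_remove``).

    The trace logs ``L_teacher``, ``L_student`` and their sum ``L_remove``
    per epoch; row 0 holds the initial full-set values before any update.
    """
    if not pairs:
        raise ValueError("distill_student needs at least one onset/apex pair")
    rng = np.random.default_rng([config.seed, 202])
    in_ch = 1 if pairs[0].onset.ndim == 2 else pairs[0].onset.shape[-1]
    student = StudentNet(config, rng, in_channels=in_ch)

    apex = as_batch(np.stack([p.apex for p in pairs]))
    onset = as_batch(np.stack([p.onset for p in pairs]))

    def full_eval() -> dict:
        lt = reconstruction_loss(onset.data, teacher(apex).data)
        ls = reconstruction_loss(onset.data, student(apex).data)
        return {"L_teacher": lt, "L_student": ls, "L_remove": lt + ls}

    trace = [dict(epoch=0, **full_eval())]
    params = student.parameters()
    if not config.freeze_teacher:
        params = params + teacher.parameters()
    opt = Adam(params, lr=config.learning_rate)

    for epoch in range(1, config.epochs + 1):
        lt_e, ls_e = [], []
        for idx in _batches(len(pairs), config.batch_size, rng):
            xb, yb = Tensor(apex.data[idx]), Tensor(onset.data[idx])
            lt = reconstruction_loss(yb, teacher(xb))
            ls = reconstruction_loss(yb, student(xb))
            loss = lt + ls
            opt.zero_grad()
            loss.backward()
            opt.step()
            lt_e.append(lt.item())
            ls_e.append(ls.item())
        row = {
            "epoch": epoch,
            "L_teacher": float(np.mean(lt_e)),
            "L_student": float(np.mean(ls_e)),
        }
        row["L_remove"] = row["L_teacher"] + row["L_student"]
        _check_finite(row["L_remove"], epoch, "L_remove")
        trace.append(row)
    return student, trace


def extract_multiscale(student: StudentNet, apex: np.ndarray) -> MultiScaleFeatureMaps:
    """Tapped encoder feature maps for one apex frame (pure function)."""
    arr = np.asarray(apex)
    batch = as_batch(arr[None, ...])
    expected_ch = student.conv1.weight.shape[1]
    if batch.shape[1] != expected_ch:
        raise ValueError(f"apex has {batch.shape[1]} channels, student expects {expected_ch}")
    feats = student.encode(batch)
    return MultiScaleFeatureMaps(maps=[f.data[0].copy() for f in feats], source=arr)
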