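"""End-to-end model: identity removal -> multi-scale attention -> fusion.

``MFVANTrainer`` wires the stages together on onset/apex samples:

1. teacher pretraining (self-reconstruction on every frame),
2. teacher/student distillation (apex -> onset, ``L_remove``),
3. joint classifier training, where the student's three encoder feature
   maps are tokenized per scale, transformer-encoded, theta-masked and
   fused, and the summed objective
   ``L_all = L_remove + L_class_global + sum_i L_class_scale,i + L_mask``
   is minimized end to end (gradients flow back into the student, and by
   default into the teacher as well).

The fused prediction ``p`` is the model's output; an optional fourth
"global" stream tokenizes the raw apex frame and joins the fusion average
with weight 1/4 (ablation switch — the default fusion averages exactly the
three feature-map scales).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .identity_removal import (
    DistillationConfig,
    ImagePair,
    StudentNet,
    TeacherNet,
    distill_student,
    pretrain_teacher,
    reconstruction_loss,
)
from .losses import LossBreakdown, LossConfig, focal_loss, inverse_frequency_alpha, mask_loss
from .nn import Adam, Module, as_batch
from .tokenizer import (
    EncoderConfig,
    FusionHead,
    ScaleOutput,
    ScaleTokenizer,
    TokenizerConfig,
    TransformerEncoder,
    encode,
    fuse_classify,
    patchify_and_embed,
)

__all__ = ["TrainConfig", "MFVANClassifier", "MFVANTrainer", "localization_scores"]


@dataclass(frozen=True)
class TrainConfig:
    """Every knob of the three-stage training pipeline."""

    distill: DistillationConfig = field(default_factory=DistillationConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    q: int = 64  # token embedding dimension
    scale_s: tuple[int, int, int] = (4, 4, 4)  # patches per side, per feature-map scale
    active_scales: tuple[int, ...] = (1, 2, 3)  # which feature-map scales are fused (ablation)
    pooling: str = "attention"  # retained-token pooling: "attention" or "mean"
    include_global_stream: bool = False  # add the raw apex frame as a 4th fused stream
    global_s: int = 8  # patch grid of the apex stream (64 px frames)
    pretrain_epochs: int = 8
    classifier_epochs: int = 20
    batch_size: int = 24
    learning_rate: float = 1e-3
    identity_removal: bool = True  # ablation: skip distillation entirely when False
    # L_teacher carries no gradient into the student or classifier, so by
    # default the teacher stays frozen during the classifier stage and its
    # loss is logged forward-only; the flag restores fully joint updates.
    train_teacher_in_joint: bool = False
    auto_alpha: bool = True  # inverse-frequency focal alpha from train labels
    seed: int = 0


class MFVANClassifier(Module):
    """Per-stream tokenizers + transformer encoders + fusion head."""

    def __init__(
        self,
        n_classes: int,
        feature_shapes: list[tuple[int, int]],  # (channels, spatial) per student scale
        apex_shape: tuple[int, int],  # (channels, spatial) of the raw frame
        config: TrainConfig,
        rng: np.random.Generator,
    ):
        self.config = config
        self.active = tuple(sorted(config.active_scales))
        if not self.active or not set(self.active) <= {1, 2, 3}:
            raise ValueError(f"active_scales must be a nonempty subset of (1,2,3), got {config.active_scales}")
        self.tokenizers = [
            ScaleTokenizer(*feature_shapes[i - 1], TokenizerConfig(s=config.scale_s[i - 1], q=config.q), rng)
            for i in self.active
        ]
        self.encoders = [TransformerEncoder(config.q, config.encoder, rng) for _ in self.active]
        if config.include_global_stream:
            self.global_tokenizer = ScaleTokenizer(
                apex_shape[0], apex_shape[1], TokenizerConfig(s=config.global_s, q=config.q), rng
            )
            self.global_encoder = TransformerEncoder(config.q, config.encoder, rng)
        else:
            self.global_tokenizer = None
            self.global_encoder = None
        n_streams = len(self.active) + (1 if config.include_global_stream else 0)
        self.head = FusionHead(config.q, n_classes, n_streams, rng)

    def streams(self, apex_batch: Tensor, feats: list[Tensor]) -> list[ScaleOutput]:
        outs = [
            encode(patchify_and_embed(feats[i - 1], tok, scale_index=i), enc)
            for i, tok, enc in zip(self.active, self.tokenizers, self.encoders)
        ]
        if self.global_tokenizer is not None:
            outs.append(encode(patchify_and_embed(apex_batch, self.global_tokenizer, scale_index=0), self.global_encoder))
        return outs


def _to_pairs(samples) -> list[ImagePair]:
    return [ImagePair(onset=s.onset_image, apex=s.apex_image) for s in samples]


class MFVANTrainer:
    """Three-stage training pipeline + prediction and attention readout."""

    def __init__(self, config: TrainConfig, classes: list[str] | None = None):
        self.config = config
        self.classes = list(classes) if classes else None
        self.teacher: TeacherNet | None = None
        self.student: StudentNet | None = None
        self.model: MFVANClassifier | None = None
        self.pretrain_trace: list[float] = []
        self.distill_trace: list[dict] = []
        self.classifier_trace: list[dict] = []

    # -- training --------------------------------------------------------
    def fit(self, samples) -> "MFVANTrainer":
        cfg = self.config
        if not samples:
            raise ValueError("no training samples")
        if self.classes is None:
            self.classes = sorted({s.label for s in samples})
        labels = [s.label for s in samples]
        y = np.array([self.classes.index(l) for l in labels])

        loss_cfg = cfg.loss
        if cfg.auto_alpha and loss_cfg.alpha is None:
            loss_cfg = replace(loss_cfg, alpha=inverse_frequency_alpha(labels, self.classes))
        dcfg = replace(cfg.distill, seed=cfg.seed)

        pairs = _to_pairs(samples)
        if cfg.identity_removal:
            all_frames = [p.onset for p in pairs] + [p.apex for p in pairs]
            pre_cfg = replace(dcfg, epochs=cfg.pretrain_epochs)
            self.teacher, self.pretrain_trace = pretrain_teacher(all_frames, pre_cfg)
            self.student, self.distill_trace = distill_student(pairs, self.teacher, dcfg)
        else:
            rng = np.random.default_rng([cfg.seed, 202])
            in_ch = 1 if pairs[0].onset.ndim == 2 else pairs[0].onset.shape[-1]
            self.student = StudentNet(dcfg, rng, in_channels=in_ch)
            self.teacher = None

        apex = as_batch(np.stack([p.apex for p in pairs]))
        onset = as_batch(np.stack([p.onset for p in pairs]))
        feats0 = self.student.encode(Tensor(apex.data[:1]))
        feature_shapes = [(f.shape[1], f.shape[2]) for f in feats0]
        apex_shape = (apex.shape[1], apex.shape[2])
        rng = np.random.default_rng([cfg.seed, 303])
        self.model = MFVANClassifier(len(self.classes), feature_shapes, apex_shape, cfg, rng)

        params = self.model.parameters() + self.student.parameters()
        use_remove = loss_cfg.use_remove and cfg.identity_removal
        if use_remove and cfg.train_teacher_in_joint:
            params = params + self.teacher.parameters()
        opt = Adam(params, lr=cfg.learning_rate)

        n = len(samples)
        order_rng = np.random.default_rng([cfg.seed, 404])
        for epoch in range(1, cfg.classifier_epochs + 1):
            sums: dict[str, float] = {}
            order = order_rng.permutation(n)
            nb = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = Tensor(apex.data[idx])
                yb = y[idx]
                feats = self.student.encode(xb)
                streams = self.model.streams(xb, feats)
                fused = fuse_classify(streams, self.model.head, pooling=cfg.pooling)
                theta = cfg.encoder.resolve_theta(streams[0].k)

                terms: list = []
                if use_remove:
                    ls = reconstruction_loss(Tensor(onset.data[idx]), self.student(xb))
                    if cfg.train_teacher_in_joint:
                        lt = reconstruction_loss(Tensor(onset.data[idx]), self.teacher(xb))
                    else:
                        lt = Tensor(np.asarray(self._teacher_loss_nograd(onset.data[idx], apex.data[idx])))
                    l_remove = lt + ls
                else:
                    l_remove = Tensor(np.asarray(0.0))
                l_global = focal_loss(fused.p, yb, loss_cfg) if loss_cfg.use_global else Tensor(np.asarray(0.0))
                active = self.model.active
                scale_losses = []
                for i in (1, 2, 3):
                    if loss_cfg.use_scale and i in active:
                        scale_losses.append(focal_loss(fused.p_scale[active.index(i)], yb, loss_cfg))
                    else:
                        scale_losses.append(Tensor(np.asarray(0.0)))
                if loss_cfg.use_mask:
                    weight_tensors = self._stream_weight_tensors(streams[: len(active)])
                    l_mask = mask_loss(weight_tensors, theta) * loss_cfg.mask_scale
                else:
                    l_mask = Tensor(np.asarray(0.0))

                total = l_remove + l_global + scale_losses[0] + scale_losses[1] + scale_losses[2] + l_mask
                opt.zero_grad()
                total.backward()
                opt.step()

                row = LossBreakdown(
                    L_remove=float(l_remove.item()),
                    L_class_global=float(l_global.item()),
                    L_class_scale=tuple(float(s.item()) for s in scale_losses),
                    L_mask=float(l_mask.item()),
                    L_all=float(total.item()),
                ).as_dict()
                for k, v in row.items():
                    sums[k] = sums.get(k, 0.0) + v
                nb += 1
            means = {k: v / nb for k, v in sums.items()}
            # log an exactly-additive breakdown: recompute the total from the means
            means["L_all"] = (
                means["L_remove"]
                + means["L_class_global"]
                + means["L_scale1"]
                + means["L_scale2"]
                + means["L_scale3"]
                + means["L_mask"]
            )
            if not np.isfinite(means["L_all"]):
                raise RuntimeError(f"L_all became non-finite at epoch {epoch}")
            self.classifier_trace.append({"epoch": epoch, **means})
        return self

    def _teacher_loss_nograd(self, onset_arr, apex_arr) -> float:
        out = self.teacher(Tensor(apex_arr)).data
        return reconstruction_loss(onset_arr, out)

    @staticmethod
    def _stream_weight_tensors(streams: list[ScaleOutput]) -> list[Tensor]:
        # differentiable attention weights, so L_mask's gradient reaches the
        # attention projections (the >= theta indicator is a constant)
        return [s.weights_t for s in streams]

    # -- inference -------------------------------------------------------
    def _forward(self, apex_images) -> tuple:
        if self.model is None:
            raise RuntimeError("trainer is not fitted")
        xb = as_batch(np.stack([np.asarray(a) for a in apex_images]))
        feats = self.student.encode(xb)
        streams = self.model.streams(xb, feats)
        fused = fuse_classify(streams, self.model.head, pooling=self.config.pooling)
        return fused, streams

    def predict(self, apex_images) -> list[str]:
        fused, _ = self._forward(apex_images)
        return [self.classes[i] for i in fused.predictions()]

    def predict_proba(self, apex_images) -> np.ndarray:
        fused, _ = self._forward(apex_images)
        return fused.p.data

    def attention_weights(self, apex_images) -> list[list[np.ndarray]]:
        """Per sample: per active feature-map scale, the (s*s,) patch weight vector."""
        _, streams = self._forward(apex_images)
        n_scales = len(self.model.active)
        return [[streams[sc].patch_weights[i] for sc in range(n_scales)] for i in range(len(apex_images))]

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        if self.model is None:
            raise RuntimeError("nothing to save: trainer is not fitted")
        arrays = {}
        for name, mod in self._named_modules():
            for i, a in enumerate(mod.state_arrays()):
                arrays[f"{name}__{i}"] = a
        meta = {"classes": self.classes, "config": _config_to_dict(self.config)}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    def _named_modules(self):
        mods = [("student", self.student), ("model", self.model)]
        if self.teacher is not None:
            mods.append(("teacher", self.teacher))
        return mods

    @classmethod
    def load(cls, path: str | Path, sample_shape: tuple[int, int] = (64, 64)) -> "MFVANTrainer":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            arrays = {k: z[k] for k in z.files if k != "__meta__"}
        config = _config_from_dict(meta["config"])
        trainer = cls(config, classes=meta["classes"])
        rng = np.random.default_rng([config.seed, 202])
        dcfg = replace(config.distill, seed=config.seed)
        trainer.student = StudentNet(dcfg, rng)
        if any(k.startswith("teacher__") for k in arrays):
            trainer.teacher = TeacherNet(dcfg, np.random.default_rng([config.seed, 101]))
        probe = np.zeros((1, 1, *sample_shape), dtype=np.float32)
        feats = trainer.student.encode(Tensor(probe))
        feature_shapes = [(f.shape[1], f.shape[2]) for f in feats]
        trainer.model = MFVANClassifier(
            len(meta["classes"]), feature_shapes, (1, sample_shape[0]), config, np.random.default_rng([config.seed, 303])
        )
        for name, mod in trainer._named_modules():
            keys = sorted(
                (k for k in arrays if k.startswith(f"{name}__")), key=lambda k: int(k.split("__")[-1])
            )
            mod.load_state_arrays([arrays[k] for k in keys])
        return trainer


def localization_scores(trainer: MFVANTrainer, samples) -> np.ndarray:
    """Per sample: attention mass on truth-mask patches minus its area share.

    For each feature-map scale the patch grid is projected onto image
    coordinates; the score averages, over the three scales, the attention
    mass falling on patches that overlap the ground-truth perturbed region
    minus the uniform baseline (the fraction of patches overlapping).
    Positive scores mean attention concentrates on the true region.
    """
    weights = trainer.attention_weights([s.apex_image for s in samples])
    scores = np.zeros(len(samples))
    for i, s in enumerate(samples):
        mask = s.truth_mask
        h = mask.shape[0]
        per_scale = []
        for sc in range(len(weights[i])):
            w = weights[i][sc]
            side = int(round(np.sqrt(w.size)))
            cell = h / side
            grid = mask.reshape(side, int(cell), side, int(cell)).sum(axis=(1, 3)) > 0
            overlap = grid.ravel()
            per_scale.append(w[overlap].sum() - overlap.mean())
        scores[i] = float(np.mean(per_scale))
    return scores


# -- config (de)serialization ---------------------------------------------

def _config_to_dict(cfg: TrainConfig) -> dict:
    return asdict(cfg)


def _config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    d["distill"] = DistillationConfig(**{**d["distill"], "scale_taps": tuple(d["distill"]["scale_taps"]),
                                         "teacher_channels": tuple(d["distill"]["teacher_channels"]),
                                         "student_channels": tuple(d["distill"]["student_channels"])})
    d["encoder"] = EncoderConfig(**d["encoder"])
    loss = dict(d["loss"])
    if loss.get("alpha") is not None:
        loss["alpha"] = tuple(loss["alpha"])
    d["loss"] = LossConfig(**loss)
    d["scale_s"] = tuple(d["scale_s"])
    return TrainConfig(**d)
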