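"""Reference study runs: distillation recovery and the LOSO benchmark.

These are the package's canonical experiments on its own synthetic data,
shared by the test suite and the reproduction script so both measure the
same protocol:

* :func:`run_distillation_study` — does apex-to-onset distillation move the
  student's output toward the neutral frame?  Reports the mean MSE of the
  student's reconstruction against the onset versus the apex-vs-onset
  baseline, and the ratio of final to initial ``L_student``.
* :func:`run_loso_study` — the full pipeline under leave-one-subject-out
  cross-validation on the default synthetic dataset (10 subjects x 12
  pairs), reporting pooled accuracy/UF1/UAR and the attention-localization
  rate (the fraction of held-out samples whose attention mass on
  truth-mask patches exceeds the uniform baseline).

Problem sizes are the package defaults; each study derives all randomness
from one integer seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .evaluation import evaluate_loso
from .identity_removal import DistillationConfig, ImagePair, distill_student, pretrain_teacher, reconstruction_loss
from .model import MFVANTrainer, TrainConfig, localization_scores
from .pipeline import stage_seed
from .synthetic import SyntheticSpec, generate_dataset
from .tokenizer import EncoderConfig

__all__ = ["study_train_config", "run_distillation_study", "run_loso_study"]

CLASSES = ["negative", "positive", "surprise"]


def study_train_config(seed: int = 0) -> TrainConfig:
    """The compact model used in the reference studies (q=64, L=2, heads=2)."""
    return TrainConfig(
        distill=DistillationConfig(epochs=10),
        encoder=EncoderConfig(L=2, heads=2),
        pretrain_epochs=3,
        classifier_epochs=20,
        seed=seed,
    )


def run_distillation_study(seed: int = 0) -> dict:
    """Teacher pretraining + distillation on the default synthetic dataset."""
    spec = replace(SyntheticSpec(), seed=stage_seed(seed, "study-synth"))
    samples, _ = generate_dataset(spec)
    pairs = [ImagePair(s.onset_image, s.apex_image) for s in samples]
    dcfg = DistillationConfig(epochs=30, seed=stage_seed(seed, "study-distill"))

    frames = [p.onset for p in pairs] + [p.apex for p in pairs]
    teacher, pre_trace = pretrain_teacher(frames, replace(dcfg, epochs=3))
    student, trace = distill_student(pairs, teacher, dcfg)

    from .nn import as_batch

    out = student(as_batch(np.stack([p.apex for p in pairs]))).data
    student_mse = float(np.mean([np.mean((o[0] - p.onset) ** 2) for o, p in zip(out, pairs)]))
    baseline_mse = float(np.mean([reconstruction_loss(p.onset, p.apex) for p in pairs]))
    return {
        "n_pairs": len(pairs),
        "student_vs_onset_mse": student_mse,
        "apex_vs_onset_mse": baseline_mse,
        "mse_improvement_ratio": student_mse / baseline_mse,
        "l_student_initial": trace[0]["L_student"],
        "l_student_final": trace[-1]["L_student"],
        "l_student_ratio": trace[-1]["L_student"] / trace[0]["L_student"],
        "distill_trace": trace,
    }


def run_loso_study(seed: int = 0, spec: SyntheticSpec | None = None, config: TrainConfig | None = None) -> dict:
    """Full LOSO benchmark on the default synthetic dataset."""
    if spec is None:
        spec = replace(SyntheticSpec(), seed=stage_seed(seed, "study-synth"))
    samples, manifest = generate_dataset(spec)
    by_id = {s.sample_id: s for s in samples}
    base_cfg = config if config is not None else study_train_config()

    fitted: list[tuple[MFVANTrainer, list]] = []

    def trainer(train_rows, test_rows, fold_seed):
        tr = [by_id[i] for i in train_rows["sample_id"]]
        te = [by_id[i] for i in test_rows["sample_id"]]
        t = MFVANTrainer(replace(base_cfg, seed=fold_seed), classes=CLASSES).fit(tr)
        fitted.append((t, te))
        return t.predict([s.apex_image for s in te])

    fold_reports, pooled, failures = evaluate_loso(
        trainer, manifest, CLASSES, seed=stage_seed(seed, "study-loso")
    )
    loc = np.concatenate([localization_scores(t, te) for t, te in fitted])
    return {
        "n_samples": len(samples),
        "n_folds": len(fold_reports),
        "failed_folds": failures,
        "pooled": pooled,
        "fold_reports": fold_reports,
        "pooled_accuracy": pooled.accuracy,
        "pooled_uf1": pooled.uf1,
        "pooled_uar": pooled.uar,
        "localization_rate": float(np.mean(loc > 0)),
        "localization_scores": loc,
    }
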