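# Methods

## Problem setting

Micro-expressions are brief, low-intensity facial muscle movements.  The
recognition task here uses exactly two frames per sample: the **onset**
frame (the subject in a neutral state — effectively an identity image) and
the **apex** frame (peak expression).  Two difficulties dominate: the
expression signal is a small, spatially localized intensity change, and it
is entangled with subject-specific appearance (identity attributes) that a
classifier must not exploit, since evaluation holds out whole subjects.

The model (MFVAN — multi-scale fusion visual attention network) addresses
both: an apex→onset mapping network suppresses identity attributes while
its encoder exposes expression-relevant features at several spatial scales,
and a per-scale transformer with attention-threshold masking drops patches
irrelevant to the expression before fusing the scales for classification.

## Identity-attribute removal

A deep **teacher** autoencoder (4 stride-2 residual conv stages, deconv
decoder) is first pretrained by plain self-reconstruction on every frame
(onset and apex), with per-pixel MSE

    L_pre = (1/NM) Σ_ij |x_ij − x'_ij|² .

Teacher and a shallow 3-stage **student** are then trained jointly to map
the apex frame to the onset frame:

    L_teacher = MSE(x_onset, teacher(x_apex))
    L_student = MSE(x_onset, student(x_apex))
    L_remove  = L_teacher + L_student .

The student decodes through skip connections plus a global residual path
from its input, and its output head is zero-initialized: at initialization
the student is exactly the identity map, so its initial loss equals the
apex-vs-onset MSE and training only learns the *correction* toward the
neutral frame.  Note that in this formulation the two reconstruction terms
are independent regressions onto the onset; the teacher influences the
student through its pretrained starting point (and shared schedule), not
through a gradient path.  Consequently the teacher is frozen by default
during the later classifier stage, where its term would only change a
logged value (`train_teacher_in_joint` restores fully joint updates).

Optimization is Adam (lr 2e-3 for pretraining/distillation, 1e-3 for the
classifier stage, no schedule).  All networks, and the transformer below,
run on the package's own reverse-mode autodiff core (`mfvan.autodiff`), a
small tape-based engine over NumPy arrays with the dozen ops the models
need; gradient correctness is checked against central finite differences
in the test suite.

## Multi-scale attention and masking

The student encoder's three feature maps (for 64 px inputs: 32², 16², 8²
with 8/16/24 channels) are each split into s×s = 4×4 patches, linearly
projected to q = 64 dims (the conv patch mapping), given learned positional
embeddings, and prepended with a per-scale learnable class token.  Each
scale runs through L pre-norm transformer blocks (multi-head self-attention
+ MLP).

**Attention weights.**  Per scale, a per-patch weight vector f_c is read
out from the encoder attention and renormalized to sum to 1.  The default
readout is *attention rollout*: the head-averaged attention matrices of all
blocks, each mixed with the identity (0.5 A + 0.5 I) to account for the
residual stream, are multiplied in order and the class-token row over patch
keys is taken.  Single-block readouts ("final", "mean") are config options;
rollout was adopted because inspecting trained models showed localization
living in specific blocks/heads, which a final-block head-average washes
out.

**θ-masking.**  Patches with weight below the threshold θ are dropped from
all downstream pooling — removed, not zero-filled.  Ties at θ count as
retained.  If no patch clears θ, the single highest-weight patch (lowest
index on ties) is kept.  The default θ is 0.8/k, i.e. slightly *below* the
uniform weight 1/k.  This choice matters for the mask loss below: because
the weights sum to 1, any θ > 1/k makes the flat, uninformative attention
distribution a global zero of the mask loss (every weight can hide below
θ), and trained models were observed to collapse to it.  With θ ≤ 1/k at
least one weight always survives, and the mask loss is instead minimized by
*concentrating* mass on few patches — the intended synergy between masking
and classification.

**Fusion.**  Each scale's retained patch tokens are pooled with their
(renormalized) attention weights — the default `attention_patches` pooling —
giving the attention a direct gradient from the classification losses;
uniform-mean pooling and a class-token-included variant are config options.
The per-scale pooled vectors are averaged with equal weight 1/3 and passed
through a small MLP + softmax to give the fused prediction p; each scale
additionally has a linear head producing p_i,scale.  An optional "global"
stream tokenizes the raw apex frame (s = 8 for 64 px frames) and joins the
average with weight 1/4 (`include_global_stream`, default off; ablation).

## Joint objective

    L_all = L_remove + L_class_global(p, y) + Σ_{i=1..3} L_class_scale,i + L_mask

with the focal classification loss

    L_class = −α_t (1 − p_t)^r log(p_t),   r = 2 by default,

α_t the per-class weight (inverse class frequency normalized to mean 1 by
default), p_t clamped at 1e−12 before the log, and the mask loss

    L_mask = Σ_scales Σ_j  { 0        if w_j < θ
                           { w_j      otherwise,

a sum over patches and scales of the attention mass that survives the
threshold.  Every component can be toggled for ablations, and L_all is
logged as the exact sum of its enabled components each epoch.

The mask loss penalizes exactly the weights the mask keeps, so it is in
tension with the classification losses that use those tokens.  Implemented
as written (a `mask_scale` factor, default 1, lets its magnitude be
studied); the θ ≤ 1/k default resolves the tension in favor of sparse,
localized attention rather than flat attention.

## Evaluation protocol

Leave-one-subject-out (LOSO) cross-validation: one fold per subject, all of
that subject's samples held out, a model trained from scratch per fold on
the rest; fold order follows sorted subject ids and per-fold seeds derive
deterministically from the run seed.  The headline report pools all
per-fold test predictions into one confusion table (MEGC convention);
per-fold reports are also emitted.  Metrics: accuracy; per-class precision,
recall and F1 with the 0/0 → 0 convention; UF1 (unweighted mean of
per-class F1); UAR (unweighted mean of per-class recall — the standard
reading of the "mean per-class accuracy" definition); and weighted F1,
since single-dataset "F1-score" conventions vary.  Dataset-native labels
can be projected onto the 3-class negative/positive/surprise scheme via an
editable vocabulary file (`mfvan/data/label_map.yaml`); unmappable labels
("others") are rejected and must be filtered explicitly.

## Synthetic data

Real micro-expression corpora are license-restricted, so the package ships
a generator that emulates their structure rather than their photometry:

* per-subject procedural identity (elliptical head, eye blobs, brow band,
  mouth bar; geometry and intensities vary per subject, capped at 0.7 so
  the perturbation cannot saturate);
* onset = identity + N(0, σ²) pixel noise, clipped to [0, 1];
* apex = onset + an additive bump of amplitude a inside a square
  region_size² mask placed in a class-specific facial band
  (negative → brow, surprise → eyes, positive → mouth, a coarse nod to
  action-unit priors), with small deterministic jitter, plus independent
  noise;
* balanced labels cycled per subject; everything a pure function of the
  spec (including its seed).

Defaults: 64×64 px, 10 subjects × 12 samples, amplitude 0.25, region 12 px,
noise σ = 0.02 — chosen so that the expression signal is low-intensity and
localized (mask covers 3.5% of the image; bump ≈ 12× the noise σ) yet the
dataset trains in minutes on one CPU.  What the generator does *not*
emulate: pose, illumination, expression-shape variability, temporal
dynamics, inter-subject correlation of expression strength.  Passing tests
on this data therefore demonstrate that the implementation recovers
planted, localized, identity-confounded signals — not field performance on
real faces.

## Reference studies and problem sizes

`mfvan.experiments` fixes the two study runs used by the tests and the
reproduction script:

* distillation study: default dataset, 3 pretrain + 30 distillation epochs;
  reports MSE(onset, student(apex)) vs MSE(onset, apex) and the final/initial
  L_student ratio;
* LOSO study: default dataset (120 samples, 10 folds), compact model
  (q = 64, L = 2, heads = 2, s = 4 per scale), 3 pretrain + 10 distillation
  + 20 classifier epochs per fold, batch 24.

## Numerical choices and degenerate inputs

* float32 training; float64 metric arithmetic; probability clamp 1e−12.
* Attention-weight renormalization guards (sum ≥ softmax output > 0).
* Empty retained set → argmax fallback; empty confusion table, empty
  training set, single-subject manifests → explicit errors.
* Checkpoints embed config and class list; loading validates array shapes.
* The `>= θ` tie rule is exact; mask-correctness is tested against a
  brute-force scan.

## Known limitations

* The autodiff core is minimal by design: no GPU, no mixed precision, no
  graph reuse; wall-clock is dominated by im2col convolutions.
* The synthetic bump is additive and single-signed; real expressions move
  texture rather than brightness.
* Attention localization is an emergent property; it is measured, not
  supervised (truth masks are never used in training), and remains the
  most seed-sensitive quantity in the studies.
* The teacher guides the student only through initialization/schedule, not
  through a distillation-specific loss term — faithful to the objective's
  definition, but it means "soft target" guidance is weaker than in
  logit-matching distillation setups.
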