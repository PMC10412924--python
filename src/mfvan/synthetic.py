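"""Synthetic onset/apex micro-expression pair generator.

Real spontaneous micro-expression corpora (SMIC, CASME II, SAMM) are
license-restricted, so this module emulates their *structure*: each sample
is a pair of face images from one subject — an onset frame (neutral,
identity only) and an apex frame (peak expression) — where the expression
manifests as a low-intensity, spatially localized intensity change.
Subjects have distinct procedural "identities" (head shape, feature
placement, base intensity), samples are grouped per subject for
leave-one-subject-out evaluation, and every sample carries a ground-truth
mask of the perturbed region so attention-localization claims can be tested
against a known target.

The class-to-region assignment is fixed: ``negative`` perturbs a brow band,
``surprise`` an eye band and ``positive`` a mouth band — a coarse nod to the
facial action units associated with those emotion groups.  The perturbation
is an additive intensity bump of fixed amplitude inside a square region,
plus i.i.d. Gaussian pixel noise drawn independently for onset and apex.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "SyntheticSample",
    "render_identity",
    "synthesize_pair",
    "generate_dataset",
]

#: vertical band centre (fraction of image height) per expression class,
#: ordered top-to-bottom: brow / eyes / mouth.
_CLASS_BANDS = {"negative": 0.20, "surprise": 0.41, "positive": 0.72}

MANIFEST_COLUMNS = ["sample_id", "subject_id", "dataset", "label", "onset_path", "apex_path"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; the whole dataset is a pure function of this."""

    image_size: int = 64
    n_subjects: int = 10
    samples_per_subject: int = 12
    class_set: tuple[str, ...] = ("negative", "positive", "surprise")
    perturbation_amplitude: float = 0.25
    region_size: int = 12
    noise_sd: float = 0.02
    seed: int = 17
    channels: int = 1  # 3 replicates the grayscale plane for RGB conv stacks

    def __post_init__(self):
        if self.perturbation_amplitude <= 0 or self.perturbation_amplitude <= 3 * self.noise_sd:
            raise ValueError(
                f"perturbation_amplitude ({self.perturbation_amplitude}) must be positive and "
                f"exceed 3*noise_sd ({3 * self.noise_sd}); the expression signal must beat noise"
            )
        if self.region_size >= self.image_size / 2:
            raise ValueError(f"region_size {self.region_size} must be < image_size/2 ({self.image_size / 2})")
        if self.n_subjects < 3:
            raise ValueError(f"n_subjects must be >= 3 for LOSO, got {self.n_subjects}")
        if len(set(self.class_set)) < 2:
            raise ValueError("class_set needs at least 2 distinct labels")
        if self.channels not in (1, 3):
            raise ValueError(f"channels must be 1 or 3, got {self.channels}")
        for label in self.class_set:
            if label not in _CLASS_BANDS:
                raise ValueError(f"no facial region assigned to class {label!r}; known: {sorted(_CLASS_BANDS)}")


@dataclass
class SyntheticSample:
    sample_id: str
    subject_id: str
    label: str
    onset_image: np.ndarray
    apex_image: np.ndarray
    truth_mask: np.ndarray


def _rng(spec: SyntheticSpec, *stream: int) -> np.random.Generator:
    """Independent generator per (seed, stream...) so draws never alias."""
    return np.random.default_rng([spec.seed, *stream])


def render_identity(subject_index: int, spec: SyntheticSpec) -> np.ndarray:
    """Procedural neutral face for one subject, deterministic per (seed, subject).

    An elliptical head, two eye blobs, a brow shade and a mouth bar whose
    geometry and intensities vary per subject.  Intensities stay below ~0.7
    so the apex bump cannot saturate against the [0, 1] clip.
    """
    if not 0 <= subject_index < spec.n_subjects:
        raise IndexError(f"subject_index {subject_index} out of range [0, {spec.n_subjects})")
    rng = _rng(spec, 0, subject_index)
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n] / (n - 1)

    bg = rng.uniform(0.10, 0.22)
    img = np.full((n, n), bg)

    # head ellipse
    cy, cx = rng.uniform(0.46, 0.54), rng.uniform(0.46, 0.54)
    ry, rx = rng.uniform(0.38, 0.46), rng.uniform(0.28, 0.36)
    head = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    img[head] = rng.uniform(0.40, 0.55)

    # eyes: dark blobs in the eye band
    ey = rng.uniform(0.38, 0.44)
    for side in (-1, 1):
        ex = cx + side * rng.uniform(0.12, 0.18)
        er = rng.uniform(0.03, 0.05)
        blob = ((yy - ey) ** 2 + (xx - ex) ** 2) <= er**2
        img[blob] = rng.uniform(0.05, 0.20)

    # brow shade: horizontal darker band above the eyes
    by = ey - rng.uniform(0.12, 0.16)
    brow = (np.abs(yy - by) < rng.uniform(0.02, 0.04)) & head
    img[brow] *= rng.uniform(0.55, 0.8)

    # mouth bar
    my = rng.uniform(0.68, 0.76)
    mw = rng.uniform(0.08, 0.14)
    mouth = (np.abs(yy - my) < 0.025) & (np.abs(xx - cx) < mw)
    img[mouth] = rng.uniform(0.15, 0.30)

    return np.clip(img, 0.0, 0.7)


def _region_slices(label: str, spec: SyntheticSpec, rng: np.random.Generator) -> tuple[slice, slice]:
    """Square perturbation region inside the class's facial band, with small jitter."""
    n, r = spec.image_size, spec.region_size
    cy = int(round(_CLASS_BANDS[label] * n))
    cx = n // 2
    # vertical jitter limited so the three class bands can never overlap
    band_gap = int(0.2 * n) - r
    jy = max(0, min(1, band_gap // 2 - 1))
    cy += rng.integers(-jy, jy + 1)
    cx += rng.integers(-3, 4)
    top = int(np.clip(cy - r // 2, 0, n - r))
    left = int(np.clip(cx - r // 2, 0, n - r))
    return slice(top, top + r), slice(left, left + r)


def synthesize_pair(
    subject_index: int, label: str, spec: SyntheticSpec, draw_index: int = 0
) -> SyntheticSample:
    """One onset/apex pair: onset = identity + noise; apex = onset + bump + noise."""
    if label not in spec.class_set:
        raise ValueError(f"unknown label {label!r}; expected one of {list(spec.class_set)}")
    identity = render_identity(subject_index, spec)
    class_index = spec.class_set.index(label)
    rng = _rng(spec, 1, subject_index, draw_index, class_index)

    n = spec.image_size
    onset = identity + rng.normal(0.0, spec.noise_sd, size=(n, n)) if spec.noise_sd > 0 else identity.copy()
    onset = np.clip(onset, 0.0, 1.0)

    ys, xs = _region_slices(label, spec, rng)
    mask = np.zeros((n, n), dtype=np.uint8)
    mask[ys, xs] = 1

    apex = onset + spec.perturbation_amplitude * mask
    if spec.noise_sd > 0:
        apex = apex + rng.normal(0.0, spec.noise_sd, size=(n, n))
    apex = np.clip(apex, 0.0, 1.0)

    if spec.channels == 3:
        onset = np.repeat(onset[:, :, None], 3, axis=2)
        apex = np.repeat(apex[:, :, None], 3, axis=2)

    return SyntheticSample(
        sample_id=f"s{subject_index:03d}_d{draw_index:03d}",
        subject_id=f"subj{subject_index:03d}",
        label=label,
        onset_image=onset,
        apex_image=apex,
        truth_mask=mask,
    )


def generate_dataset(
    spec: SyntheticSpec, out_dir: str | Path | None = None
) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """All subjects x samples_per_subject pairs, labels cycled for class balance.

    When ``out_dir`` is given, onset/apex images are written as 8-bit
    grayscale PNGs, the manifest CSV as ``manifest.csv`` and the ground-truth
    masks as ``truth_masks.npz`` (test use only); manifest paths are filled
    accordingly, otherwise left empty.
    """
    samples: list[SyntheticSample] = []
    rows = []
    for subject in range(spec.n_subjects):
        for draw in range(spec.samples_per_subject):
            label = spec.class_set[draw % len(spec.class_set)]
            s = synthesize_pair(subject, label, spec, draw_index=draw)
            samples.append(s)
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "subject_id": s.subject_id,
                    "dataset": "synthetic",
                    "label": s.label,
                    "onset_path": "",
                    "apex_path": "",
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)

    if out_dir is not None:
        from PIL import Image

        out = Path(out_dir)
        img_dir = out / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        for i, s in enumerate(samples):
            for kind in ("onset", "apex"):
                arr = getattr(s, f"{kind}_image")
                if arr.ndim == 3:
                    arr = arr[:, :, 0]
                png = img_dir / f"{s.sample_id}_{kind}.png"
                Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(png)
                manifest.loc[i, f"{kind}_path"] = str(png.relative_to(out))
        # paths are stored relative to the dataset directory, so the whole
        # dataset is relocatable and byte-identical across output locations
        manifest.to_csv(out / "manifest.csv", index=False)
        manifest[["onset_path", "apex_path"]] = manifest[["onset_path", "apex_path"]].map(
            lambda p: str(out / p)
        )
        np.savez(out / "truth_masks.npz", **{s.sample_id: s.truth_mask for s in samples})

    return samples, manifest


def spec_to_dict(spec: SyntheticSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["class_set"] = list(spec.class_set)
    return d
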