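"""Run configuration, manifest I/O and the stage orchestration layer.

A run is described by one YAML file with sections mirroring the component
configurations (``synthetic``, ``distill``, ``encoder``, ``loss``,
``train``) plus a global ``seed`` and ``out_dir``.  Unknown keys are
rejected so typos cannot silently fall back to defaults.  The global seed
fans out to per-stage seeds (stage name hashed into the seed) so stages are
individually reproducible without reusing streams.

Stages write their artifacts under ``out_dir`` together with a config-hash
sidecar; re-running with a different configuration refuses to overwrite
unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import aggregate, confusion, evaluate_loso, map_to_3class
from .identity_removal import DistillationConfig, ImagePair, distill_student, pretrain_teacher
from .losses import LossConfig
from .model import MFVANTrainer, TrainConfig, localization_scores
from .synthetic import MANIFEST_COLUMNS, SyntheticSpec, generate_dataset
from .tokenizer import EncoderConfig

__all__ = ["RunConfig", "Manifest", "load_manifest", "load_image", "run_pipeline", "stage_seed", "make_sample_trainer"]

COMMANDS = ("synth", "pretrain", "distill", "train", "evaluate")


@dataclass(frozen=True)
class RunConfig:
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    classes: tuple[str, ...] = ("negative", "positive", "surprise")
    map_labels: bool = False  # project dataset-native labels onto the 3-class scheme
    seed: int = 17
    out_dir: str = "runs/default"


def _build(cls, data: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under '{path}'")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        if name in _NESTED:
            kwargs[name] = _build(_NESTED[name], value or {}, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    "synthetic": SyntheticSpec,
    "train": TrainConfig,
    "distill": DistillationConfig,
    "encoder": EncoderConfig,
    "loss": LossConfig,
}


def load_run_config(path: str | Path | None, overrides: dict | None = None) -> RunConfig:
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    cfg = _build(RunConfig, data, "config")
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def config_hash(cfg) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def config_reference() -> str:
    """Every configuration key with its default, for ``--help`` output."""
    lines = []

    def walk(cls, prefix):
        for f in fields(cls):
            if f.name in _NESTED:
                walk(_NESTED[f.name], f"{prefix}{f.name}.")
            else:
                default = f.default if f.default is not dataclasses.MISSING else f.default_factory()
                lines.append(f"  {prefix}{f.name} = {default!r}")

    walk(RunConfig, "")
    return "Configuration keys (YAML paths) and defaults:\n" + "\n".join(lines)


# -- manifest ------------------------------------------------------------


@dataclass
class Manifest:
    """Validated sample table: one row per onset/apex pair."""

    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)


def load_manifest(path: str | Path, check_files: bool = True) -> Manifest:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest {path} is missing required column(s): {missing_cols}")
    base = Path(path).parent
    for col in ("onset_path", "apex_path"):
        df[col] = [p if (not p or Path(p).is_absolute()) else str(base / p) for p in df[col]]
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id(s) in manifest: {sorted(dup.unique())}")
    if (df["label"] == "").any():
        raise ValueError("manifest contains empty labels")
    if check_files:
        missing = [
            p
            for col in ("onset_path", "apex_path")
            for p in df[col]
            if p and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"manifest references missing file(s): {missing}")
    return Manifest(rows=df.reset_index(drop=True))


def load_image(path: str | Path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64) / 255.0


@dataclass
class LoadedSample:
    sample_id: str
    subject_id: str
    label: str
    onset_image: np.ndarray
    apex_image: np.ndarray
    truth_mask: np.ndarray | None = None


def load_samples(manifest: Manifest, map_labels: bool = False) -> list[LoadedSample]:
    out = []
    for _, r in manifest.rows.iterrows():
        label = map_to_3class(r["label"], r["dataset"]) if map_labels else r["label"]
        out.append(
            LoadedSample(
                sample_id=r["sample_id"],
                subject_id=r["subject_id"],
                label=label,
                onset_image=load_image(r["onset_path"]),
                apex_image=load_image(r["apex_path"]),
            )
        )
    return out


def make_sample_trainer(config: TrainConfig, samples_by_id: dict, classes: list[str]):
    """Adapter giving :func:`evaluate_loso` a per-fold training procedure."""

    def trainer(train_rows: pd.DataFrame, test_rows: pd.DataFrame, seed: int):
        train_samples = [samples_by_id[i] for i in train_rows["sample_id"]]
        test_samples = [samples_by_id[i] for i in test_rows["sample_id"]]
        t = MFVANTrainer(replace(config, seed=seed), classes=classes).fit(train_samples)
        trainer.fitted.append((t, test_samples))
        return t.predict([s.apex_image for s in test_samples])

    trainer.fitted = []
    return trainer


# -- stage orchestration ---------------------------------------------------


def _guard_overwrite(out: Path, cfg_hash: str, force: bool) -> None:
    sidecar = out / "config_hash.json"
    if sidecar.exists():
        prev = json.loads(sidecar.read_text())
        if prev.get("hash") != cfg_hash and not force:
            raise RuntimeError(
                f"{out} holds artifacts from config {prev.get('hash')}, current is {cfg_hash}; "
                "pass force=True / --force to overwrite"
            )
    out.mkdir(parents=True, exist_ok=True)
    sidecar.write_text(json.dumps({"hash": cfg_hash}))


def _write_trace_csv(path: Path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def run_pipeline(config: RunConfig, command: str, force: bool = False) -> dict:
    """Execute one stage; returns a summary dict of artifact paths/metrics."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; expected one of {COMMANDS}")
    out = Path(config.out_dir)
    chash = config_hash(config)
    _guard_overwrite(out, chash, force)
    run_log = {
        "command": command,
        "seed": config.seed,
        "config_hash": chash,
        "config": dataclasses.asdict(config),
    }
    (out / f"run_{command}.json").write_text(json.dumps(run_log, indent=2, default=list))

    if command == "synth":
        spec = replace(config.synthetic, seed=stage_seed(config.seed, "synth"))
        samples, manifest = generate_dataset(spec, out_dir=out)
        return {"n_samples": len(samples), "manifest": str(out / "manifest.csv")}

    manifest = load_manifest(out / "manifest.csv")
    samples = load_samples(manifest, map_labels=config.map_labels)
    pairs = [ImagePair(s.onset_image, s.apex_image) for s in samples]

    if command == "pretrain":
        dcfg = replace(config.train.distill, seed=stage_seed(config.seed, "pretrain"),
                       epochs=config.train.pretrain_epochs)
        frames = [p.onset for p in pairs] + [p.apex for p in pairs]
        teacher, trace = pretrain_teacher(frames, dcfg)
        np.savez(out / "teacher.npz", *teacher.state_arrays())
        _write_trace_csv(out / "pretrain_trace.csv", [{"epoch": i, "L_pre": v} for i, v in enumerate(trace)])
        return {"checkpoint": str(out / "teacher.npz"), "final_L_pre": trace[-1]}

    if command == "distill":
        ckpt = out / "teacher.npz"
        if not ckpt.exists():
            raise FileNotFoundError(f"distill requires a pretrained teacher checkpoint at {ckpt}")
        dcfg = replace(config.train.distill, seed=stage_seed(config.seed, "distill"))
        pre_cfg = replace(dcfg, epochs=config.train.pretrain_epochs)
        from .identity_removal import TeacherNet

        teacher = TeacherNet(pre_cfg, np.random.default_rng([pre_cfg.seed, 101]))
        with np.load(ckpt) as z:
            teacher.load_state_arrays([z[k] for k in z.files])
        student, trace = distill_student(pairs, teacher, dcfg)
        np.savez(out / "student.npz", *student.state_arrays())
        _write_trace_csv(out / "distill_trace.csv", trace)
        return {"checkpoint": str(out / "student.npz"), "final_L_remove": trace[-1]["L_remove"]}

    if command == "train":
        tcfg = replace(config.train, seed=stage_seed(config.seed, "train"))
        trainer = MFVANTrainer(tcfg, classes=list(config.classes)).fit(samples)
        trainer.save(out / "model.npz")
        _write_trace_csv(out / "classifier_trace.csv", trainer.classifier_trace)
        _write_trace_csv(
            out / "distill_trace.csv", trainer.distill_trace or [{"epoch": 0, "note": "identity removal disabled"}]
        )
        return {"checkpoint": str(out / "model.npz"), "final_L_all": trainer.classifier_trace[-1]["L_all"]}

    # evaluate: LOSO protocol (trains one model per held-out subject)
    classes = list(config.classes)
    by_id = {s.sample_id: s for s in samples}
    tcfg = replace(config.train, seed=stage_seed(config.seed, "evaluate"))
    trainer = make_sample_trainer(tcfg, by_id, classes)
    fold_reports, pooled, failures = evaluate_loso(
        trainer, manifest.rows, classes, seed=stage_seed(config.seed, "evaluate")
    )
    report = {
        "pooled": pooled.as_dict(),
        "folds": [r.as_dict() for r in fold_reports],
        "failed_folds": failures,
    }
    (out / "metrics.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    from .evaluation import loso_folds

    assignments = [
        {"sample_id": sid, "fold": subj, "role": role}
        for subj, train_ids, test_ids in loso_folds(manifest.rows).folds
        for role, ids in (("train", train_ids), ("test", test_ids))
        for sid in ids
    ]
    pd.DataFrame(assignments).to_csv(out / "fold_assignments.csv", index=False)
    return {
        "metrics": str(out / "metrics.json"),
        "pooled_accuracy": pooled.accuracy,
        "pooled_uf1": pooled.uf1,
        "pooled_uar": pooled.uar,
        "n_failed_folds": len(failures),
    }
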