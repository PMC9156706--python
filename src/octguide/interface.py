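"""Shared I/O, run configuration, logging and the command-line surface.

Frames are stored as 8-bit grayscale PNGs; a dataset is described by a CSV
manifest with columns ``subject_id, relative_path, tissue_label,
distance_um, seed`` (distance empty except for epidural-space frames) and a
sidecar ``manifest_meta.json`` provenance block carrying the generator seed
and configuration hash (or ``"external"`` for imported data).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import click
import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import cascade as cascade_mod
from . import evaluation, explain, models, synthetic_data as synth
from .synthetic_data import OCTFrame, TissueLabel

__all__ = ["Manifest", "ManifestError", "RunConfig", "read_manifest",
           "write_dataset", "scan_external_tree", "main"]

log = logging.getLogger("octguide")

MANIFEST_COLUMNS = ["subject_id", "relative_path", "tissue_label",
                    "distance_um", "seed"]


class ManifestError(ValueError):
    """Manifest missing, malformed, or referencing unreadable frames."""


@dataclass
class RunConfig:
    """Flat key/value configuration; defaults reproduce the study constants."""

    frames_per_layer: int = 1000
    subjects: int = 8
    confusable: bool = False
    window_size: int = cascade_mod.WINDOW_SIZE
    yellow_threshold: int = cascade_mod.YELLOW_THRESHOLD
    red_threshold: int = cascade_mod.RED_THRESHOLD
    learning_rate: float = 0.01
    momentum: float = 0.9
    decay: float = 0.01
    batch_size: int = 32
    patience: int = 10
    max_epochs: int = 100
    regression_epochs: int = 20
    architecture: str = "small-cnn"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def training_config(self) -> models.TrainingConfig:
        return models.TrainingConfig(
            learning_rate=self.learning_rate, momentum=self.momentum,
            decay=self.decay, batch_size=self.batch_size,
            patience=self.patience, max_epochs=self.max_epochs,
            regression_epochs=self.regression_epochs,
            architecture=self.architecture)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class Manifest:
    """Validated manifest plus lazy frame accessors."""

    root: Path
    rows: pd.DataFrame
    provenance: dict = field(default_factory=lambda: {"source": "external"})
    errors: list = field(default_factory=list)

    @property
    def subject_ids(self):
        return sorted(self.rows["subject_id"].unique())

    def load_frame(self, index: int) -> OCTFrame:
        row = self.rows.iloc[index]
        pixels = iio.imread(self.root / row["relative_path"])
        d = row["distance_um"]
        return OCTFrame(pixels=np.asarray(pixels, dtype=np.uint8),
                        subject_id=int(row["subject_id"]),
                        label=TissueLabel[row["tissue_label"]],
                        distance_um=None if pd.isna(d) else float(d))

    def load_frames(self, indices=None):
        idx = range(len(self.rows)) if indices is None else indices
        return [self.load_frame(i) for i in idx]

    def __len__(self):
        return len(self.rows)


def read_manifest(path) -> Manifest:
    """Read and validate a manifest CSV.

    Malformed rows (bad label, distance on a non-epidural frame, missing
    distance on an epidural frame, unresolvable path) are collected with
    their row numbers and reported in a single :class:`ManifestError`.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    rows = pd.read_csv(path)
    missing_cols = set(MANIFEST_COLUMNS) - set(rows.columns)
    if missing_cols:
        raise ManifestError(f"manifest header missing {sorted(missing_cols)}")
    root = path.parent
    errors = []
    for i, row in rows.iterrows():
        rowno = i + 2  # header is line 1
        label = row["tissue_label"]
        if label not in TissueLabel.__members__:
            errors.append(f"row {rowno}: unknown tissue_label {label!r}")
            continue
        has_d = not pd.isna(row["distance_um"])
        if label == "EPIDURAL_SPACE" and not has_d:
            errors.append(f"row {rowno}: epidural frame without distance_um")
        if label != "EPIDURAL_SPACE" and has_d:
            errors.append(f"row {rowno}: distance_um on a {label} frame")
        if not (root / row["relative_path"]).exists():
            errors.append(f"row {rowno}: missing file {row['relative_path']}")
    if errors:
        raise ManifestError("invalid manifest:\n  " + "\n  ".join(errors))

    meta_path = root / "manifest_meta.json"
    provenance = (json.loads(meta_path.read_text()) if meta_path.exists()
                  else {"source": "external"})
    return Manifest(root=root, rows=rows, provenance=provenance)


def write_dataset(datasets, out_dir, provenance: dict) -> Path:
    """Write frames as PNGs plus the manifest CSV and provenance sidecar.

    ``datasets`` is an iterable of (frames, seed) pairs, typically one per
    subject.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for frames, seed in datasets:
        for j, f in enumerate(frames):
            rel = Path(f"subject_{f.subject_id:02d}") / f.label.name.lower() \
                / f"frame_{j:05d}.png"
            (out / rel).parent.mkdir(parents=True, exist_ok=True)
            iio.imwrite(out / rel, f.pixels)
            records.append({
                "subject_id": f.subject_id, "relative_path": str(rel),
                "tissue_label": f.label.name,
                "distance_um": "" if f.distance_um is None else f.distance_um,
                "seed": seed})
    manifest = out / "manifest.csv"
    pd.DataFrame.from_records(records, columns=MANIFEST_COLUMNS) \
        .to_csv(manifest, index=False)
    (out / "manifest_meta.json").write_text(json.dumps(provenance, indent=2))
    return manifest


def scan_external_tree(root) -> pd.DataFrame:
    """Best-effort adapter for an externally deposited per-subject/per-layer
    directory tree: any PNG under ``<subject dir>/<layer dir>/`` is indexed
    by parsing the subject number and layer name from the directory names.
    Distances cannot be recovered this way and are left empty."""
    root = Path(root)
    aliases = {
        "fat": "FAT", "interspinous": "INTERSPINOUS_LIGAMENT",
        "ligament": "INTERSPINOUS_LIGAMENT", "flavum": "LIGAMENTUM_FLAVUM",
        "epidural": "EPIDURAL_SPACE", "cord": "SPINAL_CORD",
        "spinal": "SPINAL_CORD",
    }
    records = []
    for png in sorted(root.rglob("*.png")):
        layer_dir = png.parent.name.lower()
        subj_dir = png.parent.parent.name
        label = next((v for k, v in aliases.items() if k in layer_dir), None)
        digits = "".join(ch for ch in subj_dir if ch.isdigit())
        if label is None or not digits:
            continue
        records.append({"subject_id": int(digits),
                        "relative_path": str(png.relative_to(root)),
                        "tissue_label": label, "distance_um": "",
                        "seed": ""})
    return pd.DataFrame.from_records(records, columns=MANIFEST_COLUMNS)


# ---------------------------------------------------------------------------
# CLI


def _setup_logging(out_dir: Optional[Path] = None):
    handlers = [logging.StreamHandler(sys.stderr)]
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(out_dir / "run.log"))
    logging.basicConfig(
        level=logging.INFO, handlers=handlers, force=True,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


def _load_config(config_path, **overrides) -> RunConfig:
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    for key, val in overrides.items():
        if val is not None:
            setattr(cfg, key, val)
    log.info("effective config: %s (hash %s)", asdict(cfg), cfg.digest())
    return cfg


@click.group()
def main():
    """Computer-aided epidural needle guidance on forward-view OCT."""


@main.command()
@click.option("--subjects", type=int, default=None)
@click.option("--frames-per-layer", type=int, default=None)
@click.option("--task", type=click.Choice(["classify", "regress", "stream"]),
              default="classify")
@click.option("--out", type=click.Path(), required=True)
@click.option("--seed", type=int, default=None)
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None)
@click.option("--confusable", is_flag=True, default=None)
def simulate(subjects, frames_per_layer, task, out, seed, config_path,
             confusable):
    """Generate a synthetic labeled dataset and its manifest."""
    out = Path(out)
    _setup_logging(out)
    cfg = _load_config(config_path, subjects=subjects,
                       frames_per_layer=frames_per_layer, seed=seed,
                       confusable=confusable)
    app = (synth.confusable_appearances() if cfg.confusable
           else synth.default_appearances())
    if task == "stream":
        seq = synth.simulate_insertion_sequence(appearances=app,
                                                seed=cfg.seed)
        datasets = [(seq.frames, cfg.seed)]
    else:
        datasets = []
        for s in range(1, cfg.subjects + 1):
            sub_seed = cfg.seed + s
            ds = synth.simulate_subject(
                s, appearances=app, frames_per_layer=cfg.frames_per_layer,
                seed=sub_seed, task=task)
            datasets.append((ds.frames, sub_seed))
    manifest = write_dataset(
        datasets, out, {"source": "octguide simulate", "task": task,
                        "seed": cfg.seed, "config_hash": cfg.digest()})
    log.info("wrote %s", manifest)
    click.echo(str(manifest))


def _train_common(manifest_path, task, out, seed, config_path, arch,
                  val_subject):
    out = Path(out)
    _setup_logging(out)
    cfg = _load_config(config_path, seed=seed,
                       architecture=arch)
    man = read_manifest(manifest_path)
    frames = man.load_frames()
    subjects = man.subject_ids
    val_subject = val_subject if val_subject is not None else subjects[-1]
    train = [f for f in frames if f.subject_id != val_subject]
    val = [f for f in frames if f.subject_id == val_subject]
    tc = cfg.training_config()
    train = evaluation._task_frames(train, task)
    val = evaluation._task_frames(val, task)
    if task == "regression":
        model = models.train_regressor(tc, train, val, seed=cfg.seed)
    else:
        model = models.train_classifier(tc, task, train, val, seed=cfg.seed)
    path = out / f"{task}_{tc.architecture}.npz"
    models.save_model(model, path)
    pd.DataFrame(model.history).to_csv(out / f"{task}_history.csv",
                                       index=False)
    log.info("saved %s", path)
    click.echo(str(path))


@main.command("train-classify")
@click.option("--manifest", "manifest_path", type=click.Path(exists=True),
              required=True)
@click.option("--task", type=click.Choice(
    ["stage1", "stage2", "stage3", "stage4", "multiclass"]),
    default="stage3")
@click.option("--arch", default=None)
@click.option("--out", type=click.Path(), required=True)
@click.option("--seed", type=int, default=None)
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None)
@click.option("--val-subject", type=int, default=None)
def train_classify(manifest_path, task, arch, out, seed, config_path,
                   val_subject):
    """Train one stage (or the five-class) classifier from a manifest."""
    _train_common(manifest_path, task, out, seed, config_path, arch,
                  val_subject)


@main.command("train-regress")
@click.option("--manifest", "manifest_path", type=click.Path(exists=True),
              required=True)
@click.option("--arch", default=None)
@click.option("--out", type=click.Path(), required=True)
@click.option("--seed", type=int, default=None)
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None)
@click.option("--val-subject", type=int, default=None)
def train_regress(manifest_path, arch, out, seed, config_path, val_subject):
    """Train the needle-to-dura distance regressor from a manifest."""
    _train_common(manifest_path, "regression", out, seed, config_path, arch,
                  val_subject)


@main.command("nested-eval")
@click.option("--manifest", "manifest_path", type=click.Path(exists=True),
              required=True)
@click.option("--task", type=click.Choice(
    ["stage1", "stage2", "stage3", "stage4", "multiclass", "regression"]),
    required=True)
@click.option("--archs", default="small-cnn")
@click.option("--out", type=click.Path(), required=True)
@click.option("--seed", type=int, default=None)
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None)
def nested_eval(manifest_path, task, archs, out, seed, config_path):
    """Run the nested cross-validation/testing protocol."""
    out = Path(out)
    _setup_logging(out)
    cfg = _load_config(config_path, seed=seed)
    man = read_manifest(manifest_path)
    frames = man.load_frames()
    result = evaluation.run_nested_evaluation(
        frames, task, archs.split(","), cfg.training_config(), seed=cfg.seed)
    inner = {f"test_{t}": m for t, m in result.inner_metrics.items()}
    pd.DataFrame({k: {a: float(np.mean(v)) for a, v in d.items()}
                  for k, d in inner.items()}).to_csv(out / "inner_means.csv")
    (out / "selection.json").write_text(json.dumps(
        {str(k): v for k, v in result.selected.items()}, indent=2))
    report = evaluation.build_sequential_report(
        {task: {f"S{t}": m for t, m in result.test_metrics.items()}},
        percent=(task != "regression"))
    report.to_csv(out / "summary.csv")
    log.info("test summary: mean %.4f se %.4f", result.summary.mean,
             result.summary.se)
    click.echo(f"{result.summary.mean:.4f} ± {result.summary.se:.4f}")


@main.command("cascade-run")
@click.option("--manifest", "manifest_path", type=click.Path(exists=True),
              required=True)
@click.option("--models", "models_dir", type=click.Path(exists=True),
              default=None)
@click.option("--out", type=click.Path(), required=True)
@click.option("--oracle", is_flag=True)
def cascade_run(manifest_path, models_dir, out, oracle):
    """Run the sequential cascade over a frame stream, emit the event log."""
    out = Path(out)
    _setup_logging(out)
    man = read_manifest(manifest_path)
    frames = man.load_frames()
    if oracle:
        predictor = cascade_mod.truth_oracle_predictor
    else:
        if models_dir is None:
            raise click.UsageError("--models required unless --oracle")
        predictor = {}
        for k in (1, 2, 3, 4):
            path = Path(models_dir) / f"stage{k}_model.npz"
            if not path.exists():
                raise click.UsageError(f"missing stage model {path}")
            predictor[k] = models.load_model(path)
    annotated, switches = cascade_mod.run_stream(frames, predictor)
    payload = {
        "switches": [{"completed_stage": s, "frame": i} for s, i in switches],
        "per_frame": [{
            "frame": a.frame_index, "stage": a.stage,
            "classifier": a.classifier, "fraction": a.fraction,
            "zone": a.zone.value if a.zone else None,
            "truth": a.truth.name if a.truth is not None else None,
            "predicted": a.predicted.name} for a in annotated],
    }
    (out / "events.json").write_text(json.dumps(payload, indent=2))
    click.echo(json.dumps(payload["switches"]))


def _colormap(values: np.ndarray) -> np.ndarray:
    """Simple blue-red heat colormap for 8-bit overlay output."""
    v = np.clip(values, 0, 1)
    rgb = np.stack([v, np.clip(1 - np.abs(2 * v - 1), 0, 1), 1 - v], axis=-1)
    return (255 * rgb).astype(np.uint8)


@main.command("gradcam")
@click.option("--model", "model_path", type=click.Path(exists=True),
              required=True)
@click.option("--image", "image_path", type=click.Path(exists=True),
              required=True)
@click.option("--class", "target_class", type=int, default=1)
@click.option("--out", type=click.Path(), required=True)
def gradcam_cmd(model_path, image_path, target_class, out):
    """Write a Grad-CAM heatmap and colormapped overlay for one image."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    model = models.load_model(model_path)
    pixels = np.asarray(iio.imread(image_path), dtype=np.uint8)
    label = next(c for c in model.classes
                 if c != TissueLabel.EPIDURAL_SPACE)
    frame = OCTFrame(pixels=pixels, subject_id=0, label=label)
    heat = explain.gradcam(model, frame, target_class)
    iio.imwrite(out / "heatmap.png",
                (255 * heat.values).astype(np.uint8))
    overlay = (0.5 * _colormap(heat.values)
               + 0.5 * pixels[..., None]).astype(np.uint8)
    iio.imwrite(out / "overlay.png", overlay)
    click.echo(str(out / "heatmap.png"))


if __name__ == "__main__":
    main()
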