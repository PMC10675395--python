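"""End-to-end orchestration: simulate/read -> preprocess -> features ->
topographic images -> train/cross-validate -> report.

A :class:`PipelineConfig` (loadable from YAML, unknown keys rejected)
carries every stage's parameters plus the master seed; a run writes its
evaluation report, a manifest (config hash, seed, package versions) and
optional per-epoch artifacts into the output directory.  Identical config
and seed give identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classifier, evaluation, io, preprocess, spectral, synthetic, topomap
from .errors import ConfigurationError, InputError
from .preprocess import STATES, PreprocessConfig
from .classifier import TrainConfig

__all__ = ["PipelineConfig", "run_end_to_end", "featurize",
           "epochs_to_images", "build_corpus", "simulate_epochs"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "eegfatigue-run"
    counts: dict = field(default_factory=lambda: {s: 50 for s in STATES})
    sim_fs: float = 500.0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    apply_denoise: bool = True
    spectral_order: int = spectral.DEFAULT_ORDER
    topomap_mode: str = "band3"
    train: TrainConfig = field(default_factory=TrainConfig)
    crossval: bool = False
    save_images: bool = False
    save_features: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(dc, section, name):
            allowed = {f.name for f in dataclasses.fields(dc)}
            unknown = set(section) - allowed
            if unknown:
                raise ConfigurationError(
                    f"unknown key(s) in {name}: {sorted(unknown)}"
                )
            return dc(**section)

        raw = dict(raw)
        kwargs = {}
        if "preprocess" in raw:
            kwargs["preprocess"] = build(PreprocessConfig,
                                         raw.pop("preprocess"), "preprocess")
        if "train" in raw:
            kwargs["train"] = build(TrainConfig, raw.pop("train"), "train")
        top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - top
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def simulate_epochs(config: PipelineConfig) -> list:
    """Generate raw epochs per the configured counts and master seed."""
    return synthetic.generate_dataset(config.counts, fs=config.sim_fs,
                                      seed=config.seed)


def _preprocess_epoch(epoch, config: PipelineConfig):
    rec = preprocess.RawRecording(
        samples=epoch.samples,
        channel_labels=list(epoch.channel_labels),
        fs=epoch.fs,
        kss_timeline=[(0.0, epoch.kss)],
        subject_id=epoch.subject_id,
        state=epoch.state,
    )
    out = preprocess.preprocess_recording(
        rec, config.preprocess, apply_denoise=config.apply_denoise)
    if len(out) != 1:
        raise InputError(
            f"epoch {epoch.subject_id} did not reduce to one window"
        )
    return out[0]


def epochs_to_images(epochs, config: PipelineConfig,
                     montage: topomap.Montage | None = None,
                     preprocessed: bool = False, on_epoch=None):
    """Preprocess, featurize and render epochs; returns (X, y, features).

    X is (N, 72, 72, 3) float32, y the state labels, features the per-epoch
    band tables.  ``epochs`` may be any iterable (e.g. the lazy simulator);
    raw samples are released as soon as each image is rendered, so memory
    stays flat for large corpora.  ``on_epoch(epoch, features, image)`` is
    called per epoch when given (used for optional artifact writing).
    """
    montage = montage or topomap.standard_montage()
    images, labels, feats = [], [], []
    for ep in epochs:
        ready = ep if preprocessed else _preprocess_epoch(ep, config)
        f = spectral.extract_features(ready, order=config.spectral_order)
        img = topomap.compose_input(f, montage, mode=config.topomap_mode)
        if on_epoch is not None:
            on_epoch(ready, f, img)
        images.append(img.pixels.astype(np.float32))
        labels.append(ready.state)
        feats.append(f)
    return np.stack(images), np.array(labels), feats


def build_corpus(config: PipelineConfig, on_epoch=None):
    """Simulate and featurize the configured corpus, streaming one epoch at
    a time; returns (X, y, features)."""
    stream = synthetic.iter_dataset(config.counts, fs=config.sim_fs,
                                    seed=config.seed)
    return epochs_to_images(stream, config, on_epoch=on_epoch)


def _manifest(config: PipelineConfig, extra: dict) -> dict:
    import eegfatigue

    return {
        "package_version": getattr(eegfatigue, "__version__", "unknown"),
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **extra,
    }


def run_end_to_end(config: PipelineConfig) -> evaluation.EvaluationReport:
    """Simulate, preprocess, featurize, render, train and evaluate.

    Writes ``report.json`` and ``manifest.json`` into the output directory
    and returns the (held-out) evaluation report.  With ``crossval`` set, a
    ``crossval.json`` with per-fold reports is written too and the returned
    report is the first fold's.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("simulating and featurizing %s epochs", config.counts)

    on_epoch = None
    if config.save_features or config.save_images:
        fdir = out / "features"
        idir = out / "images"

        def on_epoch(ep, f, img):
            if config.save_features:
                fdir.mkdir(exist_ok=True)
                spectral.write_features(f, fdir / f"{ep.subject_id}.tsv")
            if config.save_images:
                idir.mkdir(exist_ok=True)
                topomap.save_png(img, idir / f"{ep.subject_id}.png")

    x, y, feats = build_corpus(config, on_epoch=on_epoch)
    per_state = {s: int((y == s).sum()) for s in STATES}
    if config.crossval:
        logger.info("running %d-fold cross-validation", config.train.folds)
        reports = classifier.kfold_cv(x, y, k=config.train.folds,
                                      config=config.train)
        (out / "crossval.json").write_text(json.dumps(
            [r.to_dict() for r in reports], indent=2))
        report = reports[0]
        mean_acc = float(np.mean([r.overall_accuracy for r in reports]))
        extra = {"cv_mean_accuracy": mean_acc,
                 "per_state_counts": per_state}
    else:
        logger.info("training on a stratified %.0f%% split",
                    100 * config.train.train_fraction)
        tr, te = classifier.split_dataset(
            y, config.train.train_fraction, config.seed)
        model = classifier.build_cnn(seed=config.seed)
        model, history = classifier.train(model, x[tr], y[tr], config.train)
        model.save(out / "model.npz")
        probs = classifier.predict_proba(model, x[te])
        report = evaluation.evaluate(y[te], probs, indices=te)
        (out / "history.tsv").write_text(
            "epoch\tloss\taccuracy\n" + "\n".join(
                f"{i}\t{l:.6f}\t{a:.6f}"
                for i, (l, a) in enumerate(zip(history["loss"],
                                               history["accuracy"]))))
        extra = {"per_state_counts": per_state}

    (out / "report.json").write_text(report.to_json(indent=2))
    (out / "manifest.json").write_text(
        json.dumps(_manifest(config, extra), indent=2))
    return report


def featurize(paths, config: PipelineConfig | None = None,
              out_dir=None) -> list:
    """Read recordings, preprocess and featurize; optionally write artifacts.

    Returns the list of (epoch, BandSpectralFeatures, TopographicImage).
    Missing or mislabelled channels raise an input error naming the
    offenders.
    """
    config = config or PipelineConfig()
    montage = topomap.standard_montage()
    results = []
    for path in paths:
        rec = io.read_recording(path)
        io.check_channels(rec.channel_labels)
        epochs = preprocess.preprocess_recording(
            rec, config.preprocess, apply_denoise=config.apply_denoise)
        for ep in epochs:
            f = spectral.extract_features(ep, order=config.spectral_order)
            img = topomap.compose_input(f, montage, mode=config.topomap_mode)
            results.append((ep, f, img))
            if out_dir is not None:
                stem = f"{ep.subject_id}_t{int(ep.start_time):05d}"
                odir = Path(out_dir)
                odir.mkdir(parents=True, exist_ok=True)
                spectral.write_features(f, odir / f"{stem}.tsv")
                topomap.save_png(img, odir / f"{stem}.png")
    return results
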