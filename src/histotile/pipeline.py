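"""End-to-end orchestration: scan -> split -> train -> extract -> select ->
classify -> evaluate, with on-disk artifacts for every stage.

A run writes to its output directory: the split manifest (TSV), the
trained backbone (.npz + JSON sidecar), the NCA weights and selection
(CSV), the feature scaler, the DeepSVM model (.npz + JSON), the training
history, and a stage-tagged run log recording every seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import deepsvm as dsvm
from . import nca as nca_mod
from .backbone import (
    BackboneConfig, BackboneTrainConfig, FeatureExtractor, FeatureMatrix,
    build_backbone, extract_features, train_backbone,
)
from .manifest import (
    DatasetManifest, SplitRatios, scan_dataset, stratified_split,
)
from .metrics import ConfusionMatrix, MetricsReport, confusion_from_predictions, confusion_metrics

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Every knob of a training run in one place."""

    split: SplitRatios = SplitRatios()
    seed: int = 0
    backbone: BackboneConfig = BackboneConfig()
    lr: float = 0.002
    max_epochs: int = 500
    batch_size: int = 64
    patience: int = 10
    k_features: int = 50
    ensemble: dsvm.EnsembleConfig = dsvm.EnsembleConfig()
    nca_max_rows: int = 800
    nca_max_iter: int = 60
    nca_blocks: nca_mod.BlockSpec | None = None

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not (1 <= self.k_features <= self.backbone.feature_dim):
            raise ValueError(
                f"k_features must lie in [1, {self.backbone.feature_dim}], "
                f"got {self.k_features}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "TrainConfig":
        """Load from a YAML (or JSON) mapping mirroring this dataclass."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "split" in raw:
            kwargs["split"] = SplitRatios(**raw.pop("split"))
        if "backbone" in raw:
            bb = raw.pop("backbone")
            for key in ("input_size", "dilation_rates"):
                if key in bb:
                    bb[key] = tuple(bb[key])
            kwargs["backbone"] = BackboneConfig(**bb)
        if "ensemble" in raw:
            kwargs["ensemble"] = dsvm.EnsembleConfig(**raw.pop("ensemble"))
        if "nca_blocks" in raw and raw["nca_blocks"] is not None:
            kwargs["nca_blocks"] = nca_mod.BlockSpec(**raw.pop("nca_blocks"))
        kwargs.update(raw)
        return cls(**kwargs)


def desk_scale_config(seed: int = 0, **overrides) -> TrainConfig:
    """A configuration sized for CPU-minutes rather than paper-scale runs."""
    defaults = dict(
        seed=seed,
        backbone=BackboneConfig(depth_preset="reduced", input_size=(64, 64),
                                feature_dim=64),
        max_epochs=25,
        patience=4,
        k_features=50,
        ensemble=dsvm.EnsembleConfig(max_layers=3, seed=seed),
    )
    defaults.update(overrides)
    return TrainConfig(**defaults)


@dataclass
class FeatureScaler:
    """Per-feature standardization fitted on the training split."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    @classmethod
    def fit(cls, x: np.ndarray) -> "FeatureScaler":
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        return cls(mean=mean, sd=np.where(sd < 1e-12, 1.0, sd))


@dataclass
class PipelineArtifacts:
    out_dir: Path
    extractor: FeatureExtractor
    scaler: FeatureScaler
    nca_weights: nca_mod.NcaWeights
    selected: nca_mod.SelectedFeatures
    model: dsvm.DeepSvmModel
    manifest: DatasetManifest
    history: dict


def _setup_run_log(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("histotile")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return handler


def _stratified_subsample(
    features: FeatureMatrix, max_rows: int, seed: int
) -> FeatureMatrix:
    n = features.values.shape[0]
    if n <= max_rows:
        return features
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    labels = np.asarray(features.labels)
    classes = np.unique(labels)
    per_class = max(2, max_rows // len(classes))
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        take = min(len(idx), per_class)
        keep.extend(rng.choice(idx, size=take, replace=False))
    keep = np.sort(np.asarray(keep))
    return FeatureMatrix(values=features.values[keep], labels=labels[keep],
                         feature_ids=list(features.feature_ids))


def run_training(
    config: TrainConfig, data_dir: str | Path, out_dir: str | Path
) -> PipelineArtifacts:
    """Execute the full training pipeline and persist all artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(out)
    t0 = time.time()
    try:
        logger.info("[scan] scanning %s", data_dir)
        manifest = scan_dataset(data_dir)
        logger.info("[scan] %d tiles in %d classes", len(manifest), manifest.n_classes)

        logger.info("[split] ratios %s seed %d", config.split, config.seed)
        manifest = stratified_split(manifest, config.split, seed=config.seed)
        manifest.save_tsv(out / "manifest.tsv")

        logger.info("[backbone] preset %s seed %d lr %g",
                    config.backbone.depth_preset, config.seed, config.lr)
        extractor = build_backbone(config.backbone, manifest.class_names,
                                   seed=config.seed)
        history = train_backbone(
            extractor, manifest,
            BackboneTrainConfig(lr=config.lr, max_epochs=config.max_epochs,
                                batch_size=config.batch_size,
                                patience=config.patience, seed=config.seed),
        )
        extractor.save(out / "backbone.npz")

        logger.info("[features] extracting train/val features")
        feats_train = extract_features(extractor, manifest, "train")
        feats_val = extract_features(extractor, manifest, "val")
        scaler = FeatureScaler.fit(feats_train.values)
        np.savez(out / "scaler.npz", mean=scaler.mean, sd=scaler.sd)

        logger.info("[nca] fitting weights (max %d rows, seed %d)",
                    config.nca_max_rows, config.seed)
        z_train = FeatureMatrix(values=scaler.transform(feats_train.values),
                                labels=feats_train.labels,
                                feature_ids=list(feats_train.feature_ids))
        nca_input = _stratified_subsample(z_train, config.nca_max_rows, config.seed)
        if config.nca_blocks is not None:
            weights = nca_mod.fit_nca_blockwise(
                nca_input, config.nca_blocks, max_iter=config.nca_max_iter,
                seed=config.seed)
        else:
            weights = nca_mod.fit_nca_weights(
                nca_input, max_iter=config.nca_max_iter, seed=config.seed)
        selected = nca_mod.select_top_k(weights, config.k_features)
        nca_mod.save_weights_csv(weights, selected, z_train.feature_ids,
                                 out / "nca_weights.csv")
        sel = np.asarray(selected.indices)
        np.savez(out / "selection.npz", indices=sel)

        logger.info("[deepsvm] training (max %d layers, seed %d)",
                    config.ensemble.max_layers, config.ensemble.seed)
        train_sel = FeatureMatrix(values=z_train.values[:, sel],
                                  labels=z_train.labels)
        val_sel = FeatureMatrix(values=scaler.transform(feats_val.values)[:, sel],
                                labels=feats_val.labels)
        model = dsvm.train_deepsvm(train_sel, val_sel,
                                   max_layers=config.ensemble.max_layers,
                                   config=config.ensemble)
        dsvm.save_deepsvm(model, out / "deepsvm.npz")

        history["wall_seconds"] = time.time() - t0
        (out / "history.json").write_text(json.dumps(history, indent=2))
        (out / "config.json").write_text(json.dumps(_config_to_jsonable(config),
                                                    indent=2))
        logger.info("[done] %.1f s; deepsvm depth %d; val acc per depth %s",
                    history["wall_seconds"], model.depth,
                    model.val_accuracy_per_depth)
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        (out / "FAILED").write_text(str(exc))
        raise
    finally:
        logging.getLogger("histotile").removeHandler(handler)
        handler.close()
    return PipelineArtifacts(out_dir=out, extractor=extractor, scaler=scaler,
                             nca_weights=weights, selected=selected,
                             model=model, manifest=manifest, history=history)


def _config_to_jsonable(config: TrainConfig) -> dict:
    d = asdict(config)
    return d


def load_artifacts(out_dir: str | Path) -> PipelineArtifacts:
    """Reload a finished run's artifacts for evaluation."""
    out = Path(out_dir)
    if (out / "FAILED").exists():
        raise ValueError(f"run in {out} is marked stale (a stage failed)")
    extractor = FeatureExtractor.load(out / "backbone.npz")
    with np.load(out / "scaler.npz") as data:
        scaler = FeatureScaler(mean=data["mean"], sd=data["sd"])
    with np.load(out / "selection.npz") as data:
        indices = tuple(int(i) for i in data["indices"])
    model = dsvm.load_deepsvm(out / "deepsvm.npz")
    manifest = DatasetManifest.load_tsv(out / "manifest.tsv")
    history = json.loads((out / "history.json").read_text())
    weights_csv = out / "nca_weights.csv"
    import pandas as pd
    wdf = pd.read_csv(weights_csv)
    weights = nca_mod.NcaWeights(w=wdf["weight"].to_numpy(), objective_trace=[],
                                 lam=0.0, sigma=1.0)
    selected = nca_mod.SelectedFeatures(indices=indices, k=len(indices))
    return PipelineArtifacts(out_dir=out, extractor=extractor, scaler=scaler,
                             nca_weights=weights, selected=selected,
                             model=model, manifest=manifest, history=history)


def evaluate(
    artifacts: PipelineArtifacts,
    manifest: DatasetManifest | None = None,
    split: str = "test",
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Preprocess -> extract -> select -> predict every tile of a split."""
    manifest = manifest if manifest is not None else artifacts.manifest
    unknown = set(manifest.class_names) - set(artifacts.extractor.class_names)
    if unknown:
        raise ValueError(f"classes {sorted(unknown)} are unknown to the model")
    feats = extract_features(artifacts.extractor, manifest, split)
    z = artifacts.scaler.transform(feats.values)[:, np.asarray(artifacts.selected.indices)]
    y_pred = dsvm.predict(artifacts.model, z)
    y_true = np.asarray([str(c) for c in feats.labels], dtype=object)
    matrix = confusion_from_predictions(y_true, y_pred,
                                        artifacts.extractor.class_names)
    return matrix, confusion_metrics(matrix)
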