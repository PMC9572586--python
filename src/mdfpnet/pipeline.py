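"""End-to-end orchestration: features -> branches -> fusion -> metrics.

Ties the modules together for the CLI and for programmatic experiments:
extracting the per-clip feature sets for a manifest, building the default
branch specifications at the features' native shapes, training the four
branches and the fusion head on one fold, and running the full holdout +
k-fold cross-validation loop with aggregated metrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .audio_io import LabelMap, ManifestRecord, read_wav
from .evaluate import ConfusionMatrix, MetricsReport, SplitPlan, aggregate_folds, confusion, make_split
from .features import FeatureConfig, FeatureSet, extract_feature_set
from .model import (
    BRANCH_ORDER,
    Branch,
    BranchSpec,
    FusionHead,
    TrainConfig,
    build_branch,
    prepare_branch_input,
    train_branch,
    train_fusion,
)
from .preprocess import PreprocessConfig, standardize

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "FoldResult",
    "CVResult",
    "default_branch_specs",
    "extract_features",
    "stack_branch_inputs",
    "run_fold",
    "run_cross_validation",
    "config_hash",
]


@dataclass(frozen=True)
class ExperimentConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    branch_epochs: int = 12
    fusion_epochs: int = 100
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    dropout: float = 0.25
    folds: int = 5
    test_frac: float = 0.20
    seed: int = 0
    backbones: dict | None = None  # feature name -> backbone identifier


def config_hash(*cfgs) -> str:
    """Stable short hash of configuration dataclasses (cache invalidation)."""
    blob = json.dumps([repr(c) for c in cfgs], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def default_branch_specs(cfg: ExperimentConfig, n_classes: int) -> dict[str, BranchSpec]:
    """Branch specs at the features' native shapes.

    The 2-D branches take frequency x time planes replicated to 3 channels;
    the 1-D branch takes the time-averaged cepstrum vector.
    """
    n_frames = 1 + cfg.preprocess.target_len // cfg.features.stft.hop
    backbones = {"mel": "tiny2d", "mfcc": "tiny2d", "lfcc": "tiny2d", "mean_mfcc": "cnn1d"}
    if cfg.backbones:
        backbones.update(cfg.backbones)
    shapes = {
        "mel": (3, cfg.features.n_filters, n_frames),
        "mfcc": (3, cfg.features.n_cepstra, n_frames),
        "lfcc": (3, cfg.features.n_cepstra, n_frames),
        "mean_mfcc": (cfg.features.n_filters,),
    }
    return {
        f: BranchSpec(feature=f, backbone=backbones[f], input_shape=shapes[f], n_classes=n_classes)
        for f in BRANCH_ORDER
    }


def extract_features(
    manifest: Sequence[ManifestRecord],
    pre_cfg: PreprocessConfig,
    feat_cfg: FeatureConfig,
    train: bool = False,
) -> list[FeatureSet]:
    """Standardize every manifest clip and compute its four features."""
    out = []
    for record in manifest:
        w = standardize(read_wav(record.path), pre_cfg, key=record.path, train=train)
        out.append(extract_feature_set(w, feat_cfg))
    return out


def stack_branch_inputs(
    features: Sequence[FeatureSet],
    specs: dict[str, BranchSpec],
) -> dict[str, np.ndarray]:
    """Per-branch input arrays stacked over clips, keyed by feature name."""
    return {
        name: np.stack([prepare_branch_input(F, spec) for F in features])
        for name, spec in specs.items()
    }


@dataclass
class FoldResult:
    fused: MetricsReport
    branch_eq6: dict[str, float]  # per-branch validation accuracy
    branch_plain: dict[str, float]
    loss_history: dict[str, list[float]]


@dataclass
class CVResult:
    folds: list[FoldResult]
    summary: dict

    def to_dict(self) -> dict:
        return {
            "folds": [
                {
                    "fused": fr.fused.to_dict(),
                    "branch_accuracy_eq6": {k: round(v, 2) for k, v in fr.branch_eq6.items()},
                }
                for fr in self.folds
            ],
            "summary": self.summary,
        }


def run_fold(
    inputs: dict[str, np.ndarray],
    labels: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    specs: dict[str, BranchSpec],
    cfg: ExperimentConfig,
    fold_seed: int,
    label_names: tuple[str, ...] | None = None,
) -> FoldResult:
    """Train the four branches and the fusion head on one fold.

    Branches train independently on the fold's training clips; they are then
    frozen and the fusion head is trained on their concatenated training-set
    outputs, starting from the averaging head.
    """
    n_classes = specs[BRANCH_ORDER[0]].n_classes
    branches: list[Branch] = []
    history: dict[str, list[float]] = {}
    val_probs: dict[str, np.ndarray] = {}
    train_probs: dict[str, np.ndarray] = {}
    for j, name in enumerate(BRANCH_ORDER):
        branch = build_branch(specs[name], seed=fold_seed * 101 + j, dropout=cfg.dropout)
        tc = TrainConfig(
            lr=cfg.lr, momentum=cfg.momentum, batch_size=cfg.batch_size,
            epochs=cfg.branch_epochs, seed=fold_seed * 31 + j, dropout=cfg.dropout,
        )
        history[name] = train_branch(branch, (inputs[name][train_idx], labels[train_idx]), tc)
        branches.append(branch)
        train_probs[name] = branch.net.predict_proba(inputs[name][train_idx].astype(np.float32))
        val_probs[name] = branch.net.predict_proba(inputs[name][val_idx].astype(np.float32))

    z_train = np.concatenate([train_probs[n] for n in BRANCH_ORDER], axis=1)
    z_val = np.concatenate([val_probs[n] for n in BRANCH_ORDER], axis=1)
    head = FusionHead.averaging(n_branches=len(BRANCH_ORDER), n_classes=n_classes)
    fusion_cfg = TrainConfig(
        lr=cfg.lr, momentum=cfg.momentum, batch_size=cfg.batch_size,
        epochs=cfg.fusion_epochs, seed=fold_seed * 17 + 7,
    )
    head, fusion_history = train_fusion(head, (z_train, labels[train_idx]), fusion_cfg)
    history["fusion"] = fusion_history

    y_val = labels[val_idx]
    fused_pred = head.predict(z_val).argmax(axis=1)
    fused_cm = confusion(y_val, fused_pred, n_classes=n_classes, labels=label_names)
    branch_eq6, branch_plain = {}, {}
    for name in BRANCH_ORDER:
        cm = confusion(y_val, val_probs[name].argmax(axis=1), n_classes=n_classes)
        report = MetricsReport(cm)
        branch_eq6[name] = report.accuracy_eq6
        branch_plain[name] = report.plain_accuracy
    return FoldResult(
        fused=MetricsReport(fused_cm),
        branch_eq6=branch_eq6,
        branch_plain=branch_plain,
        loss_history=history,
    )


def run_cross_validation(
    features: Sequence[FeatureSet],
    manifest: Sequence[ManifestRecord],
    cfg: ExperimentConfig,
    split: SplitPlan | None = None,
) -> CVResult:
    """Holdout + k-fold cross-validation of the full parallel model."""
    label_map = LabelMap.from_labels([r.label for r in manifest])
    labels = label_map.encode([r.label for r in manifest])
    specs = default_branch_specs(cfg, n_classes=len(label_map))
    inputs = stack_branch_inputs(features, specs)
    if split is None:
        split = make_split(manifest, k=cfg.folds, test_frac=cfg.test_frac, seed=cfg.seed)
    fold_results = []
    for i, (train_idx, val_idx) in enumerate(split.folds):
        logger.info("fold %d/%d: %d train / %d val", i + 1, split.k, len(train_idx), len(val_idx))
        fold_results.append(
            run_fold(inputs, labels, train_idx, val_idx, specs, cfg,
                     fold_seed=cfg.seed * 1009 + i, label_names=label_map.names)
        )
    summary = {
        "accuracy_eq6": aggregate_folds([fr.fused.accuracy_eq6 for fr in fold_results]),
        "plain_accuracy": aggregate_folds([fr.fused.plain_accuracy for fr in fold_results]),
        "branch_accuracy_eq6": {
            name: aggregate_folds([fr.branch_eq6[name] for fr in fold_results])
            for name in BRANCH_ORDER
        },
        "n_classes": len(label_map),
        "classes": list(label_map.names),
    }
    return CVResult(folds=fold_results, summary=summary)
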