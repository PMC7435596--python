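"""Metrics, split protocols and the scarce-data experiment driver.

Metrics follow the target-task evaluation conventions: accuracy, macro
average F1 (AF1) and Mean Average Precision (MAP), where a class AP is the
mean of precision-at-rank over the positions of that class's examples in
the probability-ranked test list, and MAP is the unweighted mean of the
APs defined on the test set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import KFold

from .errors import DataError, MetricError, ProtocolError
from .models import build_mdnn, build_sdnn, build_vae, forward, VAESpec
from .transfer import (TrainConfig, fine_tune, init_tto, train_sdnn,
                       train_vae, transfer_weights)

__all__ = [
    "TargetSegmentSet", "EvalReport",
    "accuracy", "average_f1", "class_ap", "mean_average_precision",
    "evaluate_model", "make_split", "downsample_training",
    "run_strategy", "downsampling_experiment", "DOWNSAMPLE_FRACTIONS",
]

DOWNSAMPLE_FRACTIONS = (0.05, 0.25, 0.50, 0.75, 1.0)


@dataclass
class TargetSegmentSet:
    """Multichannel segments with task labels and split metadata.

    ``X`` is a single ``(N, L, S)`` array or a list of per-device-group
    arrays ``(N, L_g, S_g)``; ``y`` holds integer class labels in
    ``0..C_T-1``.
    """

    X: object
    y: np.ndarray
    group_names: list = field(default_factory=lambda: ["all"])
    subjects: np.ndarray | None = None
    sessions: np.ndarray | None = None
    classes: list | None = None

    def __post_init__(self):
        if not isinstance(self.X, (list, tuple)):
            self.X = [np.asarray(self.X, dtype=float)]
        else:
            self.X = [np.asarray(x, dtype=float) for x in self.X]
        self.y = np.asarray(self.y, dtype=int)
        for x in self.X:
            if x.ndim != 3 or x.shape[0] != self.y.size:
                raise DataError("each group array must be (N, L_g, S_g) "
                                "aligned with y")
        if len(self.group_names) != len(self.X):
            raise DataError("one group name per group array required")
        for name in ("subjects", "sessions"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.size != self.y.size:
                    raise DataError(f"{name} must align with y")
                setattr(self, name, v)

    @property
    def n(self):
        return self.y.size

    @property
    def n_classes(self):
        return len(self.classes) if self.classes is not None else int(self.y.max()) + 1

    @property
    def n_channels(self):
        return sum(x.shape[2] for x in self.X)

    def inputs(self):
        return self.X

    def select(self, indices):
        indices = np.asarray(indices)
        return TargetSegmentSet(
            [x[indices] for x in self.X], self.y[indices],
            group_names=list(self.group_names),
            subjects=None if self.subjects is None else self.subjects[indices],
            sessions=None if self.sessions is None else self.sessions[indices],
            classes=self.classes)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _check_aligned(predictions, labels):
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape or predictions.size == 0:
        raise MetricError("predictions and labels must be nonempty and aligned")
    return predictions, labels


def accuracy(predictions, labels):
    predictions, labels = _check_aligned(predictions, labels)
    return float((predictions == labels).mean())


def average_f1(predictions, labels, n_classes):
    """Macro-averaged F1 over all C_T classes; a class absent from both
    predictions and labels contributes F1 = 0."""
    predictions, labels = _check_aligned(predictions, labels)
    return float(f1_score(labels, predictions, labels=np.arange(n_classes),
                          average="macro", zero_division=0))


def class_ap(scores, positives):
    """Average precision of one class over a scored test set.

    Examples are ranked by decreasing ``scores`` (ties broken by stable
    original index); precision is recorded at each rank holding a positive
    and those precisions are averaged.
    """
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    if scores.shape != positives.shape or scores.size == 0:
        raise MetricError("scores and positives must be nonempty and aligned")
    if not positives.any():
        raise MetricError("class has no positive example; AP undefined")
    order = np.argsort(-scores, kind="stable")
    ranked = positives[order]
    ranks = np.flatnonzero(ranked) + 1            # 1-based positive ranks
    precision_at = np.cumsum(ranked)[ranks - 1] / ranks
    return float(precision_at.mean())


def mean_average_precision(aps):
    """Unweighted mean of the defined class APs (dict or sequence)."""
    values = list(aps.values()) if isinstance(aps, dict) else list(aps)
    values = [v for v in values if v is not None]
    if not values:
        raise MetricError("no class has a defined AP")
    return float(np.mean(values))


@dataclass
class EvalReport:
    accuracy: float
    average_f1: float
    per_class_ap: dict
    map: float
    confusion: np.ndarray
    config: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "accuracy": self.accuracy,
            "average_f1": self.average_f1,
            "per_class_ap": {str(k): v for k, v in self.per_class_ap.items()},
            "map": self.map,
            "confusion": self.confusion.tolist(),
            "config": self.config,
        }

    def to_json(self, path=None, **kw):
        text = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate_model(network, target: TargetSegmentSet, config=None):
    """Forward the test set and compute accuracy, AF1, per-class AP and MAP."""
    probs = forward(network, target.inputs())
    n_classes = probs.shape[1]
    preds = probs.argmax(axis=1)
    aps = {}
    for c in range(n_classes):
        pos = target.y == c
        aps[c] = class_ap(probs[:, c], pos) if pos.any() else None
    return EvalReport(
        accuracy=accuracy(preds, target.y),
        average_f1=average_f1(preds, target.y, n_classes),
        per_class_ap=aps,
        map=mean_average_precision(aps),
        confusion=confusion_matrix(target.y, preds,
                                   labels=np.arange(n_classes)),
        config=dict(config or {}),
    )


# ---------------------------------------------------------------------------
# split protocols
# ---------------------------------------------------------------------------

def make_split(target: TargetSegmentSet, protocol, seed=0, n_folds=10):
    """Train/test assignments under a named protocol.

    Returns a list of ``(train_idx, test_idx)`` folds:
    ``subject_dependent`` (first session trains, later sessions test; one
    fold), ``leave_one_subject_out`` (one fold per subject) or ``kfold``
    (``n_folds`` seeded shuffled folds).
    """
    idx = np.arange(target.n)
    if protocol == "subject_dependent":
        if target.sessions is None:
            raise ProtocolError("subject_dependent split requires session tags")
        sessions = np.unique(target.sessions)
        if sessions.size < 2:
            raise ProtocolError("subject_dependent split requires >= 2 sessions")
        train = idx[target.sessions == sessions[0]]
        test = idx[target.sessions != sessions[0]]
        return [(train, test)]
    if protocol == "leave_one_subject_out":
        if target.subjects is None:
            raise ProtocolError("leave-one-subject-out requires subject ids")
        return [(idx[target.subjects != s], idx[target.subjects == s])
                for s in np.unique(target.subjects)]
    if protocol == "kfold":
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in kf.split(idx)]
    raise ProtocolError(f"unknown protocol {protocol!r}")


def downsample_training(target: TargetSegmentSet, fraction, seed=0):
    """Randomly reduce the training set to ``fraction`` of its size,
    stratified by class (per-class counts round(fraction * N_c)), sampled
    without replacement under ``seed``.  The test set is never touched."""
    if not 0 < fraction <= 1:
        raise DataError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return target
    rng = np.random.default_rng(seed)
    keep = []
    for c in np.unique(target.y):
        idx = np.flatnonzero(target.y == c)
        n_keep = int(round(fraction * idx.size))
        if n_keep == 0:
            warnings.warn(f"class {c} has zero examples after downsampling "
                          f"to {fraction:.0%}", stacklevel=2)
            continue
        keep.extend(rng.choice(idx, size=n_keep, replace=False))
    return target.select(np.sort(np.array(keep, dtype=int)))


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

def run_strategy(strategy, mdnn_spec, target_train, target_test, *,
                 source=None, seed=0, pretrain_cfg=None, finetune_cfg=None,
                 config_extra=None):
    """Run one strategy end to end and evaluate it.

    ``source`` is the modality-labelled source corpus (a single set, or a
    ``{group_name: set}`` mapping under device grouping); it is required
    for the two transfer strategies and ignored by ``tto``.
    Returns ``(report, mdnn)``.
    """
    pretrain_cfg = pretrain_cfg or TrainConfig(epochs=25, seed=seed)
    finetune_cfg = finetune_cfg or TrainConfig(epochs=30, seed=seed)
    mdnn = build_mdnn(mdnn_spec, seed=seed)
    if strategy == "tto":
        init_tto(mdnn, seed=seed)
    elif strategy in ("cnn_transfer", "vae_transfer"):
        if source is None:
            raise DataError(f"{strategy} requires a source corpus")
        sources = source if isinstance(source, dict) else \
            {g.name: source for g in mdnn_spec.groups}
        checkpoints = {}
        for g in mdnn_spec.groups:
            src = sources[g.name]
            if strategy == "cnn_transfer":
                sdnn = build_sdnn(
                    mdnn_spec.sdnn_spec(g.name, src.n_modalities), seed=seed)
                train_sdnn(sdnn, src, pretrain_cfg)
                checkpoints[g.name] = sdnn
            else:
                vae = build_vae(VAESpec(
                    g.input_length, mdnn_spec.conv_filters,
                    mdnn_spec.kernel_size, mdnn_spec.pool_size,
                    batch_norm=mdnn_spec.batch_norm), seed=seed)
                vcfg = TrainConfig(epochs=10, batch_size=pretrain_cfg.batch_size,
                                   seed=seed, loss="vae_loss")
                train_vae(vae, src, vcfg)
                checkpoints[g.name] = vae
        transfer_weights(checkpoints, mdnn)
    else:
        raise DataError(f"unknown strategy {strategy!r}")
    fine_tune(mdnn, target_train, finetune_cfg)
    config = {"strategy": strategy, "seed": seed,
              "finetune_epochs": finetune_cfg.epochs}
    config.update(config_extra or {})
    return evaluate_model(mdnn, target_test, config=config), mdnn


def downsampling_experiment(mdnn_spec, source, target_train, target_test, *,
                            strategies=("cnn_transfer", "tto"),
                            fractions=DOWNSAMPLE_FRACTIONS, seeds=(0,),
                            pretrain_cfg=None, finetune_cfg=None):
    """Scarce-label study: for every (strategy, fraction, seed), fine-tune
    on a stratified random subset of the training set and evaluate on the
    untouched test set.  Returns a list of result records."""
    records = []
    for fraction in fractions:
        for seed in seeds:
            reduced = downsample_training(target_train, fraction, seed=seed)
            for strategy in strategies:
                report, _ = run_strategy(
                    strategy, mdnn_spec, reduced, target_test, source=source,
                    seed=seed, pretrain_cfg=pretrain_cfg,
                    finetune_cfg=finetune_cfg,
                    config_extra={"training_fraction": fraction})
                records.append({
                    "strategy": strategy, "fraction": fraction, "seed": seed,
                    "n_train": reduced.n, "accuracy": report.accuracy,
                    "average_f1": report.average_f1, "map": report.map,
                })
    return records
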