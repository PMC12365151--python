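"""Stratified cross-validated training and the evaluation conventions.

Metric conventions (pinned by the degenerate all-majority baseline): macro
precision/recall/F1 with undefined per-class values set to 0, one-vs-rest
macro AUC with 0.5 for constant scores, accuracy = confusion trace / total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (confusion_matrix, precision_recall_fscore_support,
                             roc_auc_score)
from sklearn.model_selection import StratifiedKFold

from .config import ModelConfig, TrainConfig
from .fusion import CMMFNet, collate
from .losses import (class_alpha_weights, clip_contrastive_loss, focal_loss,
                     total_loss)
from .nn import Adam
from .preprocess import (EHREncoderState, PreparedCase, fit_ehr_encoder,
                         flip_with_bbox, make_roi_sample)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Macro classification metrics; accuracy/precision/recall/F1 in
    percent, AUC in [0, 1]."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    confusion: np.ndarray
    n: int

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "auc": self.auc,
                "n": self.n}


def evaluate(y_true: Sequence[int], y_pred: Sequence[int],
             scores: np.ndarray) -> MetricsReport:
    """Compute the macro metric suite from labels, predictions and
    class-probability rows (each row must sum to 1)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    scores = np.asarray(scores, dtype=np.float64)
    if not (len(y_true) == len(y_pred) == len(scores)):
        raise ValueError("labels, predictions and scores must align")
    n_classes = scores.shape[1]
    if np.any(y_true < 0) or np.any(y_true >= n_classes) \
            or np.any(y_pred < 0) or np.any(y_pred >= n_classes):
        raise ValueError("label value outside the score columns")
    if np.any(np.abs(scores.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("score rows must sum to 1")

    labels = np.arange(n_classes)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    accuracy = cm.trace() / cm.sum()
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0)
    present = np.unique(y_true)
    if len(present) < 2:
        raise ValueError("AUC needs at least two classes present")
    if len(present) < n_classes:
        # one-vs-rest over the classes that occur, probabilities renormalized
        sub = scores[:, present]
        sub = sub / sub.sum(axis=1, keepdims=True)
        remap = {c: i for i, c in enumerate(present)}
        auc = roc_auc_score(np.vectorize(remap.get)(y_true), sub,
                            multi_class="ovr", average="macro")
    else:
        auc = roc_auc_score(y_true, scores, multi_class="ovr",
                            average="macro")
    return MetricsReport(accuracy=100.0 * accuracy,
                         precision=100.0 * precision,
                         recall=100.0 * recall, f1=100.0 * f1,
                         auc=float(auc), confusion=cm, n=len(y_true))


def paired_ttest(values_a: Sequence[float],
                 values_b: Sequence[float]) -> tuple[float, float]:
    """Classic paired Student's t on per-fold metric values.

    Returns (t statistic, two-sided p-value); raises when the differences
    have zero variance (t undefined).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length paired samples, n >= 2")
    if np.std(a - b, ddof=1) == 0.0:
        raise ValueError("paired differences have zero variance; "
                         "t statistic undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# folds and training
# --------------------------------------------------------------------------

def stratified_folds(labels: Sequence[int], k: int = 5,
                     seed: int = 0) -> list[np.ndarray]:
    """k disjoint validation index sets with per-fold class counts within
    one sample of proportionality."""
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < k):
        bad = classes[counts < k]
        raise ValueError(f"classes {bad.tolist()} have fewer than {k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [val_idx for _, val_idx in skf.split(np.zeros(len(labels)), labels)]


def _augment(sample, rng: np.random.Generator, flip_prob: float):
    """Independent per-axis flips applied identically to both crop scales."""
    roi_s, box_s = sample.roi_small, sample.bbox_small
    roi_l, box_l = sample.roi_large, sample.bbox_large
    for axis in range(3):
        if rng.random() < flip_prob:
            roi_s, box_s = flip_with_bbox(roi_s, box_s, axis)
            roi_l, box_l = flip_with_bbox(roi_l, box_l, axis)
    out = type(sample)(roi_small=roi_s, roi_large=roi_l, bbox_small=box_s,
                       bbox_large=box_l, ehr_vec=sample.ehr_vec,
                       label=sample.label)
    return out


def predict(model: CMMFNet, samples, batch_size: int = 24) -> np.ndarray:
    """Class-probability rows for a list of ROISamples (inference mode)."""
    probs = []
    for start in range(0, len(samples), batch_size):
        batch = collate(samples[start:start + batch_size])
        probs.append(model.forward(batch).probabilities)
    return np.concatenate(probs, axis=0)


@dataclass
class FoldResult:
    history: pd.DataFrame
    best_state: dict[str, np.ndarray]
    best_epoch: int
    val_metrics: MetricsReport
    val_indices: np.ndarray
    val_probs: np.ndarray
    val_pred: np.ndarray
    ehr_state: EHREncoderState | None = None


def train_fold(cases: Sequence[PreparedCase], train_idx: Sequence[int],
               val_idx: Sequence[int], model_config: ModelConfig,
               train_config: TrainConfig) -> FoldResult:
    """Train on one fold and evaluate on its validation split.

    The EHR encoder is fitted on the training split only; flip augmentation
    applies to training batches only; the learning rate decays by
    ``scheduler_gamma`` per epoch; model selection keeps the epoch with the
    best validation accuracy.  Fully seeded: init, shuffling, augmentation.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    if np.intersect1d(train_idx, val_idx).size:
        raise ValueError("train and validation indices overlap")

    train_records = pd.DataFrame([cases[i].ehr_record for i in train_idx])
    state = fit_ehr_encoder(train_records)
    cfg = model_config.with_ehr_len(state.length)

    train_samples = [make_roi_sample(cases[i], state) for i in train_idx]
    val_samples = [make_roi_sample(cases[i], state) for i in val_idx]
    train_labels = np.asarray([s.label for s in train_samples])
    counts = np.bincount(train_labels, minlength=cfg.n_classes)
    if np.any(counts == 0):
        raise ValueError("every class must appear in the training split")
    alpha_t = class_alpha_weights(counts)

    rng = np.random.default_rng(train_config.seed)
    model = CMMFNet(cfg, rng)
    optimizer = Adam(model.named_parameters(), lr=train_config.lr,
                     betas=train_config.betas,
                     weight_decay=train_config.weight_decay)
    use_contrastive = ("clinical" in cfg.modalities
                       and ("small" in cfg.modalities
                            or "large" in cfg.modalities))

    history_rows = []
    best_acc, best_epoch, best_state = -1.0, -1, model.state_dict()
    n_train = len(train_samples)
    for epoch in range(train_config.epochs):
        optimizer.lr = train_config.lr_at_epoch(epoch)
        order = rng.permutation(n_train)
        step_logs = []
        for start in range(0, n_train, train_config.batch_size):
            chunk = [train_samples[i] for i in order[start:start
                                                     + train_config.batch_size]]
            if train_config.augment:
                chunk = [_augment(s, rng, train_config.flip_prob)
                         for s in chunk]
            batch = collate(chunk)
            out = model.forward(batch)
            l_focal = focal_loss(out.logits, batch["labels"],
                                 alpha_t=alpha_t, gamma=0.25)
            if use_contrastive:
                zero = 0.0
                l_sc = (clip_contrastive_loss(
                    out.l1, labels=batch["labels"],
                    targets=cfg.contrastive_targets)
                    if out.l1 is not None else zero)
                l_lc = (clip_contrastive_loss(
                    out.l2, labels=batch["labels"],
                    targets=cfg.contrastive_targets)
                    if out.l2 is not None else zero)
                bundle = total_loss(l_sc, l_lc, l_focal)
            else:
                bundle = total_loss(0.0, 0.0, l_focal)
            if not np.isfinite(bundle.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"contrastive=({bundle.contrastive_small}, "
                    f"{bundle.contrastive_large}) focal={bundle.focal}")
            optimizer.zero_grad()
            bundle._total_tensor.backward()
            optimizer.step()
            step_logs.append(bundle)

        val_probs = predict(model, val_samples, train_config.batch_size)
        val_pred = val_probs.argmax(axis=1)
        val_true = np.asarray([s.label for s in val_samples])
        val_acc = float((val_pred == val_true).mean())
        history_rows.append({
            "epoch": epoch, "lr": optimizer.lr,
            "loss_total": np.mean([b.total for b in step_logs]),
            "loss_contrastive_small": np.mean(
                [b.contrastive_small for b in step_logs]),
            "loss_contrastive_large": np.mean(
                [b.contrastive_large for b in step_logs]),
            "loss_focal": np.mean([b.focal for b in step_logs]),
            "omega": np.mean([b.omega for b in step_logs]),
            "val_accuracy": 100.0 * val_acc,
        })
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    val_probs = predict(model, val_samples, train_config.batch_size)
    val_pred = val_probs.argmax(axis=1)
    val_true = np.asarray([s.label for s in val_samples])
    report = evaluate(val_true, val_pred, val_probs)
    return FoldResult(history=pd.DataFrame(history_rows),
                      best_state=best_state, best_epoch=best_epoch,
                      val_metrics=report, val_indices=val_idx,
                      val_probs=val_probs, val_pred=val_pred,
                      ehr_state=state)


@dataclass
class CVResult:
    fold_results: list[FoldResult]
    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    mean: dict[str, float]
    sd: dict[str, float]


def cross_validate(cases: Sequence[PreparedCase], model_config: ModelConfig,
                   train_config: TrainConfig, k: int = 5) -> CVResult:
    """Stratified k-fold protocol: each fold trains an independently
    initialized model and validates on its held-out split; reports per-fold
    metrics, their mean +- sd, and pooled-prediction metrics."""
    labels = [c.label for c in cases]
    folds = stratified_folds(labels, k=k, seed=train_config.seed)
    all_idx = np.arange(len(cases))
    results: list[FoldResult] = []
    for fold_no, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, val_idx)
        fold_cfg = TrainConfig(**{**train_config.__dict__,
                                  "seed": train_config.seed + fold_no})
        results.append(train_fold(cases, train_idx, val_idx,
                                  model_config, fold_cfg))

    pooled_true = np.concatenate([np.asarray(labels)[r.val_indices]
                                  for r in results])
    pooled_pred = np.concatenate([r.val_pred for r in results])
    pooled_probs = np.concatenate([r.val_probs for r in results])
    pooled = evaluate(pooled_true, pooled_pred, pooled_probs)

    reports = [r.val_metrics for r in results]
    keys = ("accuracy", "precision", "recall", "f1", "auc")
    mean = {k_: float(np.mean([getattr(r, k_) for r in reports]))
            for k_ in keys}
    sd = {k_: float(np.std([getattr(r, k_) for r in reports], ddof=1))
          for k_ in keys}
    return CVResult(fold_results=results, fold_reports=reports,
                    pooled=pooled, mean=mean, sd=sd)


# --------------------------------------------------------------------------
# bookkeeping
# --------------------------------------------------------------------------

def count_parameters(model_or_config: CMMFNet | ModelConfig
                     ) -> tuple[int, dict[str, int]]:
    """Exact learnable-scalar count, itemized by top-level parameter group."""
    if isinstance(model_or_config, ModelConfig):
        cfg = model_or_config
        if cfg.ehr_len is None and "clinical" in cfg.modalities:
            cfg = cfg.with_ehr_len(8)
        model = CMMFNet(cfg, np.random.default_rng(0))
    else:
        model = model_or_config
    groups: dict[str, int] = {}
    seen: dict[int, str] = {}
    for name, p in model.named_parameters().items():
        if id(p) in seen:        # shared weights are counted once
            continue
        seen[id(p)] = name
        group = name.split(".")[0]
        groups[group] = groups.get(group, 0) + int(p.data.size)
    return sum(groups.values()), groups
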