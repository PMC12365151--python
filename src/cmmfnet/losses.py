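"""Training objective: symmetric contrastive loss, focal loss with
inverse-frequency class weights, and the dynamically weighted total.

The dynamic weight omega = Lc / (Lc + Lf) (with Lc the summed contrastive
terms and Lf the focal term) is recomputed from the current detached loss
values each step, so whichever objective is currently larger is down-
weighted; substituting it into the weighted sum gives the closed form
L_total = (Lc^2 + Lf^2) / (Lc + Lf).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from ._tensor import Tensor
from .types import LossBundle

logger = logging.getLogger(__name__)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor.const(np.asarray(x, dtype=np.float64))


def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor.const(logits.data.max(axis=axis, keepdims=True))
    shifted = logits - shift
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, target_index: np.ndarray) -> Tensor:
    """Mean cross-entropy of row i against integer target target_index[i]."""
    n, c = logits.shape
    onehot = np.zeros((n, c))
    onehot[np.arange(n), np.asarray(target_index, dtype=int)] = 1.0
    return -(log_softmax(logits) * Tensor.const(onehot)).sum(axis=-1).mean()


def clip_contrastive_loss(l: Tensor | np.ndarray,
                          labels: Sequence[int] | None = None,
                          targets: str = "pair") -> Tensor:
    """Symmetric cross-entropy over an N x N similarity matrix.

    Row i of ``l`` scores case i's image feature against every clinical
    feature in the batch; with ``targets="pair"`` (the CLIP reading) the
    correct column is i itself, and the loss averages the row-wise and
    column-wise cross-entropies.  ``targets="class"`` treats all same-class
    cases as positives (uniform target distribution over them); it requires
    ``labels``.
    """
    l = _as_tensor(l)
    if l.ndim != 2 or l.shape[0] != l.shape[1]:
        raise ValueError(f"similarity logits must be square, got {l.shape}")
    n = l.shape[0]
    if targets == "pair":
        idx = np.arange(n)
        return (cross_entropy(l, idx) + cross_entropy(l.swapaxes(0, 1), idx)) * 0.5
    if targets == "class":
        if labels is None:
            raise ValueError("class-level targets require labels")
        labels = np.asarray(labels, dtype=int)
        if labels.shape != (n,):
            raise ValueError("labels length must match the batch")
        t = (labels[:, None] == labels[None, :]).astype(np.float64)
        t /= t.sum(axis=1, keepdims=True)
        tt = Tensor.const(t)
        loss_rows = -(log_softmax(l) * tt).sum(axis=-1).mean()
        loss_cols = -(log_softmax(l.swapaxes(0, 1)) * tt).sum(axis=-1).mean()
        return (loss_rows + loss_cols) * 0.5
    raise ValueError(f"unknown contrastive target mode {targets!r}")


def class_alpha_weights(label_counts: Sequence[int]) -> np.ndarray:
    """Inverse-frequency class weights, normalized so a balanced dataset
    gives all-ones: alpha[c] = N_total / (n_classes * count[c])."""
    counts = np.asarray(label_counts, dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError("every class needs a positive count")
    return counts.sum() / (len(counts) * counts)


def focal_loss(logits: Tensor | np.ndarray, labels: Sequence[int],
               alpha_t: Sequence[float] | None = None,
               gamma: float = 0.25) -> Tensor:
    """Mean of alpha_t * (1 - p_t)^gamma * (-log p_t) over the batch.

    gamma defaults to 0.25, the reference setting for this task (canonical
    focal loss uses 2); gamma = 0 with unit alpha reduces exactly to mean
    cross-entropy.
    """
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty batch")
    n, c = logits.shape
    if labels.shape != (n,):
        raise ValueError("labels length must match the batch")
    if np.any(labels < 0) or np.any(labels >= c):
        raise ValueError("label out of range")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    alpha = np.ones(c) if alpha_t is None else np.asarray(alpha_t, dtype=np.float64)
    if alpha.shape != (c,) or np.any(alpha <= 0) or not np.isfinite(alpha).all():
        raise ValueError("alpha_t must be positive and finite, one per class")

    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    oh = Tensor.const(onehot)
    p_t = (logits.softmax(axis=-1) * oh).sum(axis=-1)
    log_p_t = (log_softmax(logits) * oh).sum(axis=-1)
    weight = Tensor.const(alpha[labels])
    modulator = (1.0 - p_t) ** gamma if gamma > 0 else 1.0
    return (weight * modulator * (-log_p_t)).mean()


def dynamic_weight(contrastive_sum: float, focal: float) -> float:
    """omega = Lc / (Lc + Lf) from detached loss values (no gradient)."""
    lc, lf = float(contrastive_sum), float(focal)
    if lc < 0 or lf < 0:
        raise ValueError("losses must be non-negative")
    if lc + lf == 0.0:
        logger.warning("both loss terms are zero; falling back to omega = 0.5")
        return 0.5
    return lc / (lc + lf)


def total_loss(contrastive_small: Tensor | float,
               contrastive_large: Tensor | float,
               focal: Tensor | float) -> LossBundle:
    """Combine the three terms with the dynamic weight.

    omega is computed from the current detached values, so the combined
    objective carries gradients only through the loss terms themselves.
    Returns a LossBundle whose ``_total_tensor`` supports backward().
    """
    sc, lc, fo = (_as_tensor(x) for x in (contrastive_small,
                                          contrastive_large, focal))
    for name, t in (("contrastive_small", sc), ("contrastive_large", lc),
                    ("focal", fo)):
        if float(t.data) < -1e-12:
            raise ValueError(f"{name} must be non-negative")
    omega = dynamic_weight(float(sc.data) + float(lc.data), float(fo.data))
    total = (sc + lc) * omega + fo * (1.0 - omega)
    return LossBundle(contrastive_small=float(sc.data),
                      contrastive_large=float(lc.data),
                      focal=float(fo.data), omega=omega,
                      total=float(total.data), _total_tensor=total)
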