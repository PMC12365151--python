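"""Contrastive alignment and the two-phase deep feature fusion (DFF).

Alignment is CLIP-style: per-modality features are L2-normalized and paired
cosine similarities are scaled by a learnable temperature initialized at
exp(log 1/0.07).  Fusion treats the three modality features as a 3-token
sequence: Phase 1 runs transformer blocks over it and normalizes per token;
Phase 2 applies channel attention — average- and max-pooled per-channel
statistics pass through a shared two-layer bottleneck, the two sigmoid gates
are summed, and each modality row is rescaled by its gate.  A linear head on
the flattened stack produces the three class logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, concat, l2_normalize_rows, layer_norm
from .config import ModelConfig
from .encoders import ClinicalEncoder, CTEncoder
from .nn import Linear, Module, TransformerBlock

INIT_LOG_SCALE = float(np.log(1.0 / 0.07))


def l2_normalize(f: Tensor | np.ndarray) -> Tensor:
    """Divide each feature row by its Euclidean norm (z = f / ||f||)."""
    if not isinstance(f, Tensor):
        f = Tensor.const(np.asarray(f, dtype=np.float64))
    return l2_normalize_rows(f)


def similarity_logits(z_a: Tensor | np.ndarray, z_b: Tensor | np.ndarray,
                      log_scale: Tensor | float = INIT_LOG_SCALE) -> Tensor:
    """Temperature-scaled cosine similarities l[i, j] = exp(log_scale) *
    <z_a[i], z_b[j]> between unit-norm feature rows."""
    if not isinstance(z_a, Tensor):
        z_a = Tensor.const(np.asarray(z_a, dtype=np.float64))
    if not isinstance(z_b, Tensor):
        z_b = Tensor.const(np.asarray(z_b, dtype=np.float64))
    if z_a.shape[-1] != z_b.shape[-1]:
        raise ValueError("feature dimension mismatch")
    for z in (z_a, z_b):
        norms = np.linalg.norm(z.data, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-5):
            raise ValueError("similarity_logits expects unit-norm rows")
    if not isinstance(log_scale, Tensor):
        log_scale = Tensor.const(log_scale)
    return log_scale.exp() * (z_a @ z_b.swapaxes(-1, -2))


def dff_phase1(F: Tensor, blocks: list[TransformerBlock],
               norm: str = "layernorm") -> Tensor:
    """Run the fusion transformer stack and normalize the output.

    ``norm`` selects the final normalization: per-token layer normalization
    (no affine) or a plain L2 row normalization.
    """
    if len(blocks) < 1:
        raise ValueError("phase 1 needs at least one transformer block")
    x = F
    for block in blocks:
        x = block(x)
    if norm == "layernorm":
        return layer_norm(x)
    if norm == "l2":
        return l2_normalize_rows(x)
    raise ValueError(f"unknown phase-1 norm {norm!r}")


class ChannelAttention(Module):
    """Sigmoid-gated channel reweighting over the modality axis.

    Average and max pooling over the feature axis give two per-channel
    summaries; both pass through the shared bottleneck W2 @ ReLU(W1 @ s)
    and a sigmoid; the per-channel multiplier is the sum of the two gates,
    so it lies in (0, 2) and equals exactly 1 when all weights are zero.
    """

    def __init__(self, n_channels: int, reduction_ratio: int,
                 rng: np.random.Generator):
        super().__init__()
        if reduction_ratio < 1 or n_channels % reduction_ratio != 0:
            raise ValueError("reduction ratio must divide the channel count")
        hidden = n_channels // reduction_ratio
        self.w1 = Linear(n_channels, hidden, rng, bias=False)
        self.w2 = Linear(hidden, n_channels, rng, bias=False)

    def gate(self, pooled: Tensor) -> Tensor:
        return self.w2(self.w1(pooled).relu()).sigmoid()

    def __call__(self, F_p1: Tensor) -> Tensor:
        ap = F_p1.mean(axis=-1)                      # (B, C)
        mp = F_p1.max(axis=-1)
        multiplier = self.gate(ap) + self.gate(mp)   # in (0, 2)
        b, c = multiplier.shape
        return F_p1 * multiplier.reshape(b, c, 1)


def classify(F_p2: Tensor, head: Linear) -> Tensor:
    """Flatten the fused C x D stack and map it to class logits."""
    b = F_p2.shape[0]
    return head(F_p2.reshape(b, F_p2.shape[1] * F_p2.shape[2]))


@dataclass
class ModelOutput:
    """Forward-pass results: class logits, the two contrastive logit
    matrices (None when a pairing is not available), the raw fused stack
    and the per-modality features."""

    logits: Tensor
    l1: Tensor | None
    l2: Tensor | None
    fused: Tensor
    features: dict[str, Tensor]

    @property
    def probabilities(self) -> np.ndarray:
        return self.logits.softmax(axis=-1).data


class CMMFNet(Module):
    """The full multimodal classifier.

    Two ViT CT encoders (one per crop scale, optionally weight-shared), a
    fully connected clinical encoder, CLIP-style alignment between each CT
    scale and the clinical feature, and the two-phase DFF fusion head.
    ``config.modalities`` and ``config.use_dff`` expose the ablation
    variants as pure configuration.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        if "clinical" in config.modalities and config.ehr_len is None:
            raise ValueError("config.ehr_len must be set before building "
                             "a model with the clinical modality")
        self.config = config
        d = config.embed_dim

        if "small" in config.modalities:
            self.cte_small = CTEncoder(config, config.crop_small, rng,
                                       use_bbox_token=config.use_bbox_token)
        if "large" in config.modalities:
            if config.share_cte and "small" in config.modalities:
                shared = self.cte_small
                self.cte_large = CTEncoder(
                    config, config.crop_large, rng,
                    use_bbox_token=config.use_bbox_token,
                    blocks=shared.blocks, patch_proj=shared.patch_proj,
                    bbox_proj=(shared.bbox_proj if config.use_bbox_token
                               else None))
            else:
                self.cte_large = CTEncoder(config, config.crop_large, rng,
                                           use_bbox_token=config.use_bbox_token)
        if "clinical" in config.modalities:
            self.cle = ClinicalEncoder(config.ehr_len, d, rng)

        self.log_scale = Tensor(np.asarray(INIT_LOG_SCALE),
                                requires_grad=not config.freeze_temperature)
        if config.freeze_temperature:
            # kept out of named_parameters so the optimizer never moves it
            object.__setattr__(self, "log_scale", Tensor(
                np.asarray(INIT_LOG_SCALE), requires_grad=False))

        n_ch = len(config.modalities)
        if config.use_dff:
            self.dff_blocks = [TransformerBlock(d, config.dff_heads, rng,
                                                mlp_ratio=config.mlp_ratio,
                                                ffn=config.ffn)
                               for _ in range(config.dff_layers)]
            self.channel_attention = ChannelAttention(
                n_ch, config.reduction_ratio, rng)
        self.head = Linear(n_ch * d, config.n_classes, rng)

    # -- forward --------------------------------------------------------------
    def forward(self, batch: dict[str, np.ndarray]) -> ModelOutput:
        """Run a collated batch through encoders, alignment and fusion.

        ``batch`` holds "roi_small"/"roi_large" crops, "bbox_small"/
        "bbox_large" relative 6-vectors and "ehr" encoded records, as
        produced by :func:`collate`.
        """
        cfg = self.config
        feats: dict[str, Tensor] = {}
        if "small" in cfg.modalities:
            feats["small"] = self.cte_small(
                batch["roi_small"],
                batch["bbox_small"] if cfg.use_bbox_token else None)
        if "large" in cfg.modalities:
            feats["large"] = self.cte_large(
                batch["roi_large"],
                batch["bbox_large"] if cfg.use_bbox_token else None)
        if "clinical" in cfg.modalities:
            feats["clinical"] = self.cle(batch["ehr"])
        if not feats:
            raise ValueError("no modality enabled")

        l1 = l2 = None
        if "clinical" in feats:
            z_c = l2_normalize(feats["clinical"])
            if "small" in feats:
                l1 = similarity_logits(l2_normalize(feats["small"]), z_c,
                                       self.log_scale)
            if "large" in feats:
                l2 = similarity_logits(l2_normalize(feats["large"]), z_c,
                                       self.log_scale)

        # classification pathway consumes the raw (un-normalized) features
        stack = concat([feats[m].reshape(feats[m].shape[0], 1,
                                         cfg.embed_dim)
                        for m in cfg.modalities], axis=1)
        if cfg.use_dff:
            fused = dff_phase1(stack, self.dff_blocks, cfg.phase1_norm)
            fused = self.channel_attention(fused)
        else:
            fused = stack
        logits = classify(fused, self.head)
        return ModelOutput(logits=logits, l1=l1, l2=l2, fused=stack,
                           features=feats)

    __call__ = forward


def collate(samples) -> dict[str, np.ndarray]:
    """Stack a list of ROISample objects into batch arrays."""
    if not samples:
        raise ValueError("empty batch")
    return {
        "roi_small": np.stack([s.roi_small for s in samples]),
        "roi_large": np.stack([s.roi_large for s in samples]),
        "bbox_small": np.stack([s.bbox_small.as_vector() for s in samples]),
        "bbox_large": np.stack([s.bbox_large.as_vector() for s in samples]),
        "ehr": np.stack([s.ehr_vec.values for s in samples]),
        "labels": np.asarray([s.label for s in samples], dtype=int),
    }
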