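"""Model and training configuration with YAML round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import yaml

MODALITIES = ("small", "clinical", "large")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference configuration: 768-dim embeddings, 12
    transformer layers with 12 heads and patch size 8 in the CT encoders,
    a 2-layer fusion transformer and channel attention with reduction
    ratio 1 over the three modality channels.
    """

    embed_dim: int = 768
    depth: int = 12
    n_heads: int = 12
    patch_size: int = 8
    mlp_ratio: float = 4.0
    ehr_len: int | None = None          # filled in once the EHR encoder is fit
    dff_layers: int = 2
    dff_heads: int | None = None        # defaults to n_heads
    reduction_ratio: int = 1
    share_cte: bool = False
    freeze_temperature: bool = False
    ffn: bool = True
    phase1_norm: str = "layernorm"      # "layernorm" | "l2"
    contrastive_targets: str = "pair"   # "pair" | "class"
    crop_small: tuple[int, int, int] = (32, 32, 32)
    crop_large: tuple[int, int, int] = (128, 128, 32)
    modalities: tuple[str, ...] = MODALITIES
    use_dff: bool = True
    use_bbox_token: bool = True
    n_classes: int = 3

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.dff_heads is None:
            self.dff_heads = self.n_heads
        if self.embed_dim % self.dff_heads != 0:
            raise ValueError("embed_dim must be divisible by dff_heads")
        if self.dff_layers < 1:
            raise ValueError("dff_layers must be >= 1")
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        n_ch = len(self.modalities)
        if n_ch < 1 or any(m not in MODALITIES for m in self.modalities):
            raise ValueError(f"modalities must be a subset of {MODALITIES}")
        if self.reduction_ratio < 1 or n_ch % self.reduction_ratio != 0 \
                or n_ch // self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must divide the channel count")
        if self.phase1_norm not in ("layernorm", "l2"):
            raise ValueError("phase1_norm must be 'layernorm' or 'l2'")
        if self.contrastive_targets not in ("pair", "class"):
            raise ValueError("contrastive_targets must be 'pair' or 'class'")
        self.crop_small = tuple(int(c) for c in self.crop_small)
        self.crop_large = tuple(int(c) for c in self.crop_large)
        self.modalities = tuple(self.modalities)

    def with_ehr_len(self, ehr_len: int) -> "ModelConfig":
        return replace(self, ehr_len=int(ehr_len))

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["crop_small"] = list(self.crop_small)
        d["crop_large"] = list(self.crop_large)
        d["modalities"] = list(self.modalities)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @staticmethod
    def from_yaml(path: str | Path) -> "ModelConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("crop_small", "crop_large", "modalities"):
            if key in d:
                d[key] = tuple(d[key])
        return ModelConfig(**d)


@dataclass
class TrainConfig:
    """Optimizer and schedule settings.

    The reference schedule is Adam at lr 1e-4, weight decay 1e-3, betas
    (0.9, 0.99), per-epoch exponential decay 0.99, batch size 24, 500 epochs.
    The desk-scale default keeps the optimizer but runs 30 epochs.
    """

    lr: float = 1e-4
    weight_decay: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.99)
    scheduler_gamma: float = 0.99
    epochs: int = 30
    batch_size: int = 24
    flip_prob: float = 0.5
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if not (0.0 < self.scheduler_gamma < 1.0):
            raise ValueError("scheduler_gamma must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        self.betas = tuple(self.betas)

    def lr_at_epoch(self, epoch: int) -> float:
        return self.lr * self.scheduler_gamma ** epoch


def tiny_model_config(ehr_len: int | None = None, **overrides) -> ModelConfig:
    """A desk-scale configuration: 64-dim embeddings, 2 encoder layers,
    4 heads, 1 fusion layer, reduced crops (16^3 and 32x32x16)."""
    base = dict(embed_dim=64, depth=2, n_heads=4, patch_size=8,
                dff_layers=1, crop_small=(16, 16, 16),
                crop_large=(32, 32, 16), ehr_len=ehr_len)
    base.update(overrides)
    return ModelConfig(**base)
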