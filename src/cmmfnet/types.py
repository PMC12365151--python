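"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

VOXEL_ABSOLUTE = "voxel-absolute"
CROP_RELATIVE = "crop-relative"


@dataclass
class CTVolume:
    """A 3D CT grid in Hounsfield units with anisotropic voxel spacing."""

    voxels: np.ndarray                      # rank-3, HU (or [0,1] after windowing)
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume.voxels must be rank-3")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be three positive values")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BBox3D:
    """A lesion bounding box, center + size, in a declared coordinate frame.

    In the ``voxel-absolute`` frame center/size are voxel indices and counts;
    in the ``crop-relative`` frame all six values lie in [0, 1] (fractions of
    the crop extent along each axis).
    """

    center: tuple[float, float, float]
    size: tuple[float, float, float]
    frame: str = VOXEL_ABSOLUTE

    def __post_init__(self):
        self.center = tuple(float(c) for c in self.center)
        self.size = tuple(float(s) for s in self.size)
        if self.frame not in (VOXEL_ABSOLUTE, CROP_RELATIVE):
            raise ValueError(f"unknown bbox frame {self.frame!r}")
        if any(s <= 0 for s in self.size):
            raise ValueError("bbox size must be positive on every axis")
        if self.frame == CROP_RELATIVE:
            vals = (*self.center, *self.size)
            if any(v < 0.0 or v > 1.0 for v in vals):
                raise ValueError("crop-relative bbox values must lie in [0, 1]")

    def as_vector(self) -> np.ndarray:
        """(x, y, z, w, h, d) as a flat float vector."""
        return np.asarray([*self.center, *self.size], dtype=np.float64)


@dataclass
class EHRVector:
    """Encoded clinical record: z-scored numerics + one-hot categoricals."""

    values: np.ndarray
    field_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if len(self.values) != len(self.field_names):
            raise ValueError("values and field_names length mismatch")


@dataclass
class ROISample:
    """One training case: dual-scale normalized crops, relative boxes,
    encoded clinical vector and the subtype label (0=AIS, 1=MIA, 2=IA)."""

    roi_small: np.ndarray
    roi_large: np.ndarray
    bbox_small: BBox3D
    bbox_large: BBox3D
    ehr_vec: EHRVector
    label: int

    def __post_init__(self):
        for name in ("roi_small", "roi_large"):
            grid = np.asarray(getattr(self, name), dtype=np.float64)
            if grid.min() < -1e-9 or grid.max() > 1.0 + 1e-9:
                raise ValueError(f"{name} intensities must lie in [0, 1]")
            setattr(self, name, grid)
        for name in ("bbox_small", "bbox_large"):
            if getattr(self, name).frame != CROP_RELATIVE:
                raise ValueError(f"{name} must be crop-relative")
        self.label = int(self.label)


@dataclass
class SyntheticCase:
    """A generated lesion phantom with its box, clinical record and label."""

    volume: CTVolume
    bbox: BBox3D
    ehr: dict[str, Any]
    label: int


@dataclass
class ModalFeature:
    """A 1xD (or batch x D) embedding from one modality."""

    vector: np.ndarray
    modality: str  # "small-CT" | "clinical" | "large-CT"

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.isfinite(self.vector).all():
            raise ValueError("modal feature contains non-finite values")


@dataclass
class LossBundle:
    """The four loss scalars, the dynamic weight and the combined objective.

    Invariant: ``total = omega * (sc + lc) + (1 - omega) * focal``.
    """

    contrastive_small: float
    contrastive_large: float
    focal: float
    omega: float
    total: float
    _total_tensor: Any = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        for name in ("contrastive_small", "contrastive_large", "focal", "total"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"loss term {name} must be non-negative")
        if not (0.0 <= self.omega <= 1.0):
            raise ValueError("omega must lie in [0, 1]")
        recomputed = (self.omega * (self.contrastive_small + self.contrastive_large)
                      + (1.0 - self.omega) * self.focal)
        if abs(recomputed - self.total) > 1e-9:
            raise ValueError("total loss inconsistent with its components")
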