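"""Class-conditional 3D lesion phantoms with boxes and correlated clinical records.

The generator emulates the radiology narrative of the three adenocarcinoma
subtypes: in-situ lesions are small, faint (ground-glass) and smooth; invasive
lesions are large, dense (solid) and spiculated.  Each phantom is a radially
perturbed sphere placed in a uniform lung field, so its support — and hence
its tight bounding box — has a closed form that tests can check exactly.

Everything is driven by a single :class:`PhantomSpec` plus a seed: identical
(spec, seed) pairs reproduce identical datasets bit for bit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .types import BBox3D, CTVolume, SyntheticCase

HU_FLOOR = -1000.0
HU_SPAN = 1400.0        # intensity in [0,1] maps to HU = -1000 + 1400 * intensity
HU_BACKGROUND = -900.0  # aerated lung parenchyma


class LesionOutOfBoundsError(ValueError):
    """The requested lesion cannot fit inside the volume with a safe margin."""


@dataclass
class EHRField:
    """One clinical field of the synthetic record schema.

    ``kind`` is "numeric" or "categorical".  Numeric fields draw
    Normal(class_means[label] + radius_coeff * lesion_radius_mm, noise_sd);
    categorical fields draw a category from per-class probability rows.
    """

    name: str
    kind: str
    class_means: tuple[float, ...] | None = None
    radius_coeff: float = 0.0
    noise_sd: float = 1.0
    categories: tuple[str, ...] | None = None
    class_probs: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self):
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"unknown EHR field kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.categories or not self.class_probs:
                raise ValueError(f"categorical field {self.name!r} needs "
                                 "categories and class_probs")
            for row in self.class_probs:
                if abs(sum(row) - 1.0) > 1e-9:
                    raise ValueError(f"class_probs rows of {self.name!r} "
                                     "must sum to 1")


def default_ehr_schema() -> list[EHRField]:
    """Age, sex, smoking status, measured nodule diameter and a serum marker.

    Exercises both encodings (numeric + categorical); the diameter field is
    correlated with the true lesion radius so the clinical modality alone
    carries class signal, as it does in real cohorts.
    """
    return [
        EHRField("age", "numeric", class_means=(55.0, 62.0, 68.0), noise_sd=8.0),
        EHRField("sex", "categorical", categories=("M", "F"),
                 class_probs=((0.50, 0.50), (0.45, 0.55), (0.40, 0.60))),
        EHRField("smoking", "categorical",
                 categories=("never", "former", "current"),
                 class_probs=((0.6, 0.3, 0.1), (0.45, 0.35, 0.2),
                              (0.3, 0.4, 0.3))),
        EHRField("nodule_diameter_mm", "numeric", class_means=(0.0, 0.0, 0.0),
                 radius_coeff=2.0, noise_sd=1.0),
        EHRField("marker_level", "numeric", class_means=(1.0, 2.0, 3.5),
                 noise_sd=0.8),
    ]


@dataclass
class PhantomSpec:
    """Study conditions for the phantom cohort.

    Per-class defaults follow the ground-glass -> solid progression:
    mean radii 4 / 7 / 11 mm, interior intensities 0.35 / 0.55 / 0.80
    (HU -510 / -230 / +120 after the fixed intensity*1400 - 1000 mapping),
    spiculation amplitudes 0 / 0.15 / 0.35.
    """

    n_classes: int = 3
    class_probs: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    lesion_radius_mean_mm: tuple[float, ...] = (4.0, 7.0, 11.0)
    lesion_intensity_mean: tuple[float, ...] = (0.35, 0.55, 0.80)
    spiculation_amp: tuple[float, ...] = (0.0, 0.15, 0.35)
    radius_jitter: float = 0.15         # radius ~ U(mean*(1-j), mean*(1+j))
    noise_sd: float = 0.05              # Gaussian noise, intensity units
    ehr_schema: list[EHRField] = field(default_factory=default_ehr_schema)
    volume_shape_vox: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_classes != 3:
            raise ValueError("the subtype task is fixed at 3 classes")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if len(self.class_probs) != self.n_classes:
            raise ValueError("class_probs length must equal n_classes")
        for attr in ("lesion_radius_mean_mm", "lesion_intensity_mean",
                     "spiculation_amp"):
            if len(getattr(self, attr)) != self.n_classes:
                raise ValueError(f"{attr} needs one value per class")
        if any(r <= 0 for r in self.lesion_radius_mean_mm):
            raise ValueError("lesion radii must be strictly positive")
        if any(a < 0 for a in self.spiculation_amp):
            raise ValueError("spiculation amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        self._check_margins()

    def _check_margins(self) -> None:
        for c in range(self.n_classes):
            r_max = (self.lesion_radius_mean_mm[c] * (1 + self.radius_jitter)
                     * (1 + self.spiculation_amp[c]))
            for ax in range(3):
                extent = self.volume_shape_vox[ax] * self.spacing_mm[ax]
                if 2 * r_max + 2 * self.spacing_mm[ax] > extent:
                    raise LesionOutOfBoundsError(
                        f"class {c} lesion (max radius {r_max:.1f} mm) does not "
                        f"fit inside axis {ax} extent {extent:.1f} mm")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["ehr_schema"] = [asdict(f) for f in self.ehr_schema]
        return d

    @staticmethod
    def from_dict(d: dict[str, Any]) -> "PhantomSpec":
        d = dict(d)
        d["ehr_schema"] = [EHRField(**f) for f in d.get("ehr_schema", [])]
        for key in ("class_probs", "lesion_radius_mean_mm",
                    "lesion_intensity_mean", "spiculation_amp",
                    "volume_shape_vox", "spacing_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return PhantomSpec(**d)


def _harmonic_perturbation(theta: np.ndarray, phi: np.ndarray,
                           phases: np.ndarray) -> np.ndarray:
    """Fixed low-order spherical harmonic bump pattern, bounded in [-1, 1]."""
    return 0.5 * (np.sin(3.0 * theta + phases[0]) * np.cos(2.0 * phi + phases[1])
                  + np.cos(2.0 * theta + phases[2]))


def sample_label(spec: PhantomSpec, rng: np.random.Generator) -> int:
    return int(rng.choice(spec.n_classes, p=np.asarray(spec.class_probs)))


def sample_case(spec: PhantomSpec, label: int,
                rng: np.random.Generator) -> SyntheticCase:
    """Draw one phantom of the given class.

    The lesion is a radially perturbed sphere, r(theta, phi) =
    r0 * (1 + amp * P(theta, phi)) with P a fixed low-order harmonic pattern
    (random phases per case).  Interior intensity maps to HU via
    intensity * 1400 - 1000; the background is uniform lung at -900 HU.
    Gaussian noise of sd ``noise_sd`` (intensity units) is added everywhere.
    """
    if not (0 <= label < spec.n_classes):
        raise ValueError(f"label {label} out of range")
    shape = np.asarray(spec.volume_shape_vox)
    spacing = np.asarray(spec.spacing_mm)

    r0 = spec.lesion_radius_mean_mm[label] * rng.uniform(
        1 - spec.radius_jitter, 1 + spec.radius_jitter)
    amp = spec.spiculation_amp[label]
    r_max = r0 * (1 + amp)
    margin_vox = np.ceil(r_max / spacing) + 1
    lo, hi = margin_vox, shape - 1 - margin_vox
    if np.any(lo > hi):
        raise LesionOutOfBoundsError(
            f"lesion radius {r_max:.1f} mm leaves no valid center "
            f"inside volume {tuple(shape)} at spacing {tuple(spacing)}")
    center = rng.uniform(lo, hi)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)

    idx = np.indices(tuple(shape)).astype(np.float64)
    delta = (idx - center.reshape(3, 1, 1, 1)) * spacing.reshape(3, 1, 1, 1)
    rho = np.sqrt((delta ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(rho > 0, delta[2] / rho, 1.0),
                                  -1.0, 1.0))
    phi = np.arctan2(delta[1], delta[0])
    radius_field = r0 * (1.0 + amp * _harmonic_perturbation(theta, phi, phases))
    mask = rho <= radius_field

    intensity = spec.lesion_intensity_mean[label]
    hu = np.full(tuple(shape), HU_BACKGROUND)
    hu[mask] = HU_FLOOR + HU_SPAN * intensity
    if spec.noise_sd > 0:
        hu += HU_SPAN * spec.noise_sd * rng.standard_normal(tuple(shape))

    support = np.argwhere(mask)
    if support.size == 0:
        raise LesionOutOfBoundsError("lesion support is empty (radius below "
                                     "voxel resolution)")
    lo_idx = support.min(axis=0)
    hi_idx = support.max(axis=0)
    bbox = BBox3D(center=tuple((lo_idx + hi_idx) / 2.0),
                  size=tuple(hi_idx - lo_idx + 1.0))

    ehr: dict[str, Any] = {}
    for f in spec.ehr_schema:
        if f.kind == "numeric":
            mean = f.class_means[label] + f.radius_coeff * r0
            ehr[f.name] = float(mean + f.noise_sd * rng.standard_normal())
        else:
            probs = np.asarray(f.class_probs[label])
            ehr[f.name] = str(rng.choice(list(f.categories), p=probs))

    volume = CTVolume(voxels=hu, spacing_mm=tuple(spacing))
    return SyntheticCase(volume=volume, bbox=bbox, ehr=ehr, label=label)


def apportion_counts(probs: Sequence[float], n: int) -> np.ndarray:
    """Nearest-integer apportionment of ``n`` items to ``probs`` shares
    (largest-remainder method)."""
    probs = np.asarray(probs, dtype=np.float64)
    exact = probs * n
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:remainder]] += 1
    return counts


def merge_counts(counts: Sequence[int],
                 groups: Sequence[Sequence[int]]) -> np.ndarray:
    """Merge raw subtype counts into grouped class counts.

    Example: the 4-subtype cohort (AAH, AIS, MIA, IA) merges AAH into AIS via
    groups ((0, 1), (2,), (3,)).
    """
    counts = np.asarray(counts)
    return np.asarray([counts[list(g)].sum() for g in groups])


def class_fractions(counts: Sequence[int]) -> np.ndarray:
    counts = np.asarray(counts, dtype=np.float64)
    return counts / counts.sum()


def build_dataset(spec: PhantomSpec, n_cases: int, out_dir: str | Path,
                  seed: int | None = None) -> pd.DataFrame:
    """Generate ``n_cases`` phantoms, write NIfTI volumes + a CSV manifest.

    Label assignment is stratified: per-class counts follow ``class_probs``
    by largest-remainder apportionment, then the case order is shuffled.
    Returns the manifest (also written to ``out_dir/manifest.csv``); the spec
    is serialized alongside as ``phantom_spec.yaml``.
    """
    import nibabel as nib
    import yaml

    if n_cases < spec.n_classes:
        raise ValueError("need at least one case per class")
    if not spec.ehr_schema:
        raise ValueError("ehr_schema must not be empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    counts = apportion_counts(spec.class_probs, n_cases)
    labels = np.repeat(np.arange(spec.n_classes), counts)
    labels = labels[rng.permutation(n_cases)]

    rows = []
    for i, label in enumerate(labels):
        case = sample_case(spec, int(label), rng)
        case_id = f"case_{i:05d}"
        path = out_dir / f"{case_id}.nii.gz"
        affine = np.diag([*case.volume.spacing_mm, 1.0])
        nib.save(nib.Nifti1Image(case.volume.voxels.astype(np.float32),
                                 affine), str(path))
        row = {"case_id": case_id, "label": int(label),
               "cx": case.bbox.center[0], "cy": case.bbox.center[1],
               "cz": case.bbox.center[2], "w": case.bbox.size[0],
               "h": case.bbox.size[1], "d": case.bbox.size[2],
               "frame": case.bbox.frame}
        row.update(case.ehr)
        row["path"] = str(path)
        rows.append(row)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    with open(out_dir / "phantom_spec.yaml", "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)
    return manifest


def manifest_checksum(manifest: pd.DataFrame) -> str:
    """Stable digest of a manifest's contents (order-sensitive)."""
    return hashlib.sha256(
        manifest.to_csv(index=False).encode()).hexdigest()
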