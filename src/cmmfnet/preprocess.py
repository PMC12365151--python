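"""CT and clinical-record preparation.

The imaging path mirrors standard lung-CT practice: resample every scan to
isotropic 1 mm voxels, window intensities to [-1000, 400] HU and rescale to
[0, 1], then cut two lesion-centred blocks per case — a tight 32^3 crop and a
contextual 128x128x32 crop — carrying the lesion box along in crop-relative
coordinates.  Flip augmentation mirrors grid and box together.

Clinical records are encoded as z-scored numerics plus one-hot categoricals;
the statistics are fitted on the training split only so folds never leak.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from sklearn.preprocessing import OneHotEncoder

from .types import (BBox3D, CROP_RELATIVE, CTVolume, EHRVector, ROISample,
                    VOXEL_ABSOLUTE)

logger = logging.getLogger(__name__)

HU_WINDOW = (-1000.0, 400.0)
CROP_SMALL = (32, 32, 32)
CROP_LARGE = (128, 128, 32)


# --------------------------------------------------------------------------
# volume I/O
# --------------------------------------------------------------------------

def load_nifti(path: str | Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    voxels = np.asanyarray(img.dataobj).astype(np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return CTVolume(voxels=voxels, spacing_mm=spacing, origin_mm=origin)


def load_dicom_series(directory: str | Path) -> CTVolume:
    """Read an axial DICOM series into a CTVolume (slices sorted by position)."""
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files under {directory}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    hu = np.stack([s.pixel_array * float(getattr(s, "RescaleSlope", 1.0))
                   + float(getattr(s, "RescaleIntercept", 0.0))
                   for s in slices], axis=-1).astype(np.float64)
    ps = [float(x) for x in slices[0].PixelSpacing]
    if len(slices) > 1:
        dz = abs(float(slices[1].ImagePositionPatient[2])
                 - float(slices[0].ImagePositionPatient[2]))
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    return CTVolume(voxels=hu, spacing_mm=(ps[0], ps[1], dz), origin_mm=origin)


# --------------------------------------------------------------------------
# imaging ops
# --------------------------------------------------------------------------

def resample_to_isotropic(volume: CTVolume,
                          target_spacing_mm: Sequence[float] = (1.0, 1.0, 1.0)
                          ) -> CTVolume:
    """Trilinear resampling to the target spacing.

    Output shape per axis is round(in_shape * in_spacing / target); the voxel
    at output index i samples input coordinate i * target / in_spacing.
    """
    target = np.asarray(target_spacing_mm, dtype=np.float64)
    if target.shape != (3,) or np.any(target <= 0):
        raise ValueError("target spacing must be three positive values")
    spacing = np.asarray(volume.spacing_mm)
    in_shape = np.asarray(volume.shape)
    out_shape = np.rint(in_shape * spacing / target).astype(int)
    if np.any(out_shape < 1):
        raise ValueError("target spacing coarser than the volume extent")

    grids = np.meshgrid(*[np.arange(n) * t / s
                          for n, t, s in zip(out_shape, target, spacing)],
                        indexing="ij")
    coords = np.stack([g.ravel() for g in grids])
    resampled = map_coordinates(volume.voxels, coords, order=1,
                                mode="nearest").reshape(tuple(out_shape))
    return CTVolume(voxels=resampled, spacing_mm=tuple(target),
                    origin_mm=volume.origin_mm)


def window_and_normalize(volume: CTVolume, lo_hu: float = HU_WINDOW[0],
                         hi_hu: float = HU_WINDOW[1]) -> CTVolume:
    """Clip to [lo_hu, hi_hu] and rescale linearly to [0, 1]."""
    if hi_hu <= lo_hu:
        raise ValueError("hi_hu must exceed lo_hu")
    if not np.isfinite(volume.voxels).all():
        raise ValueError("volume contains non-finite voxels")
    v = np.clip(volume.voxels, lo_hu, hi_hu)
    v = (v - lo_hu) / (hi_hu - lo_hu)
    return CTVolume(voxels=v, spacing_mm=volume.spacing_mm,
                    origin_mm=volume.origin_mm)


def crop_centered_roi(volume: CTVolume | np.ndarray, bbox: BBox3D,
                      crop_shape: Sequence[int]
                      ) -> tuple[np.ndarray, BBox3D]:
    """Cut a fixed-shape block centred on the lesion box.

    Out-of-volume regions are padded with 0 (the post-windowing value of
    -1000 HU air).  The returned box is crop-relative: center' =
    (center - crop_origin) / crop_shape and size' = size / crop_shape,
    both clamped to [0, 1].
    """
    grid = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume)
    if bbox.frame != VOXEL_ABSOLUTE:
        raise ValueError("crop_centered_roi expects a voxel-absolute bbox")
    crop_shape = tuple(int(c) for c in crop_shape)
    if any(c <= 0 for c in crop_shape):
        raise ValueError("crop shape must be positive")
    if any(c > 4 * n for c, n in zip(crop_shape, grid.shape)):
        raise ValueError(f"crop shape {crop_shape} exceeds 4x volume "
                         f"extent {grid.shape}")
    center = np.asarray(bbox.center, dtype=np.float64)
    if np.any(center < 0) or np.any(center >= np.asarray(grid.shape)):
        raise ValueError("bbox center lies outside the volume")

    origin = np.floor(center + 0.5).astype(int) - np.asarray(crop_shape) // 2
    crop = np.zeros(crop_shape, dtype=grid.dtype)
    src_lo = np.maximum(origin, 0)
    src_hi = np.minimum(origin + crop_shape, grid.shape)
    dst_lo = src_lo - origin
    dst_hi = dst_lo + (src_hi - src_lo)
    crop[tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))] = \
        grid[tuple(slice(a, b) for a, b in zip(src_lo, src_hi))]

    rel_center = np.clip((center - origin) / crop_shape, 0.0, 1.0)
    rel_size = np.clip(np.asarray(bbox.size) / crop_shape, 1e-9, 1.0)
    rel_box = BBox3D(center=tuple(rel_center), size=tuple(rel_size),
                     frame=CROP_RELATIVE)
    return crop, rel_box


def relative_to_absolute(bbox: BBox3D, crop_origin: Sequence[float],
                         crop_shape: Sequence[int]) -> BBox3D:
    """Invert the crop-relative mapping given the same crop geometry."""
    if bbox.frame != CROP_RELATIVE:
        raise ValueError("expected a crop-relative bbox")
    shape = np.asarray(crop_shape, dtype=np.float64)
    center = np.asarray(bbox.center) * shape + np.asarray(crop_origin)
    size = np.asarray(bbox.size) * shape
    return BBox3D(center=tuple(center), size=tuple(size), frame=VOXEL_ABSOLUTE)


def flip_with_bbox(grid: np.ndarray, bbox: BBox3D,
                   axis: int) -> tuple[np.ndarray, BBox3D]:
    """Mirror the crop along one axis and reflect the box center with it."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    if bbox.frame != CROP_RELATIVE:
        raise ValueError("flip_with_bbox expects a crop-relative bbox")
    flipped = np.flip(grid, axis=axis).copy()
    center = list(bbox.center)
    center[axis] = 1.0 - center[axis]
    return flipped, BBox3D(center=tuple(center), size=bbox.size,
                           frame=CROP_RELATIVE)


# --------------------------------------------------------------------------
# clinical-record encoding
# --------------------------------------------------------------------------

@dataclass
class EHREncoderState:
    numeric_fields: list[str]
    numeric_mean: dict[str, float]
    numeric_sd: dict[str, float]
    categorical_fields: list[str]
    vocabularies: dict[str, list[str]]
    field_order: list[str]           # original schema order
    feature_names: list[str]         # expanded output columns

    @property
    def length(self) -> int:
        return len(self.feature_names)


def fit_ehr_encoder(records: pd.DataFrame,
                    schema: Sequence[tuple[str, str]] | None = None
                    ) -> EHREncoderState:
    """Learn standardization stats and one-hot vocabularies from the
    training split only.

    ``schema`` is an ordered list of (field name, "numeric"|"categorical");
    if omitted it is inferred from the dtypes.  Numeric sd uses the
    population convention (ddof=0).  Unseen categories at encode time map to
    an all-zeros one-hot group.
    """
    if schema is None:
        schema = [(c, "numeric" if pd.api.types.is_numeric_dtype(records[c])
                   else "categorical") for c in records.columns]
    missing = [name for name, _ in schema if name not in records.columns]
    if missing:
        raise ValueError(f"schema fields missing from records: {missing}")

    numeric_fields = [n for n, k in schema if k == "numeric"]
    categorical_fields = [n for n, k in schema if k == "categorical"]
    mean, sd = {}, {}
    for name in numeric_fields:
        col = records[name].to_numpy(dtype=np.float64)
        m, s = float(col.mean()), float(col.std(ddof=0))
        if s == 0.0:
            raise ValueError(f"numeric field {name!r} has zero variance "
                             "on the fitting split")
        mean[name], sd[name] = m, s

    vocabularies: dict[str, list[str]] = {}
    if categorical_fields:
        enc = OneHotEncoder(handle_unknown="ignore", sparse_output=False)
        enc.fit(records[categorical_fields].astype(str))
        vocabularies = {name: [str(c) for c in cats] for name, cats
                        in zip(categorical_fields, enc.categories_)}

    feature_names: list[str] = []
    for name, kind in schema:
        if kind == "numeric":
            feature_names.append(name)
        else:
            feature_names.extend(f"{name}={c}" for c in vocabularies[name])
    return EHREncoderState(numeric_fields=numeric_fields, numeric_mean=mean,
                           numeric_sd=sd, categorical_fields=categorical_fields,
                           vocabularies=vocabularies,
                           field_order=[n for n, _ in schema],
                           feature_names=feature_names)


def encode_ehr(record: Mapping[str, Any],
               state: EHREncoderState) -> EHRVector:
    """z-score numerics, one-hot categoricals, in the fitted schema order."""
    values: list[float] = []
    for name in state.field_order:
        if name not in record:
            raise ValueError(f"record is missing field {name!r}")
        if name in state.numeric_fields:
            values.append((float(record[name]) - state.numeric_mean[name])
                          / state.numeric_sd[name])
        else:
            vocab = state.vocabularies[name]
            value = str(record[name])
            onehot = [0.0] * len(vocab)
            if value in vocab:
                onehot[vocab.index(value)] = 1.0
            else:
                warnings.warn(f"unseen category {value!r} for field {name!r}; "
                              "encoding as all-zeros")
            values.extend(onehot)
    return EHRVector(values=np.asarray(values), field_names=state.feature_names)


def encode_ehr_table(records: pd.DataFrame,
                     state: EHREncoderState) -> np.ndarray:
    return np.stack([encode_ehr(row, state).values
                     for row in records.to_dict("records")])


# --------------------------------------------------------------------------
# per-case pipeline
# --------------------------------------------------------------------------

@dataclass
class PreparedCase:
    """Crops + relative boxes + raw clinical record, before EHR encoding.

    Encoding is deferred so cross-validation can fit the standardization on
    each training fold only.
    """

    case_id: str
    roi_small: np.ndarray
    roi_large: np.ndarray
    bbox_small: BBox3D
    bbox_large: BBox3D
    ehr_record: dict[str, Any]
    label: int


def prepare_case(volume: CTVolume, bbox: BBox3D, ehr_record: Mapping[str, Any],
                 label: int, case_id: str = "",
                 crop_small: Sequence[int] = CROP_SMALL,
                 crop_large: Sequence[int] = CROP_LARGE,
                 resample: bool = True) -> PreparedCase:
    """resample -> window -> dual-scale crop for one case."""
    if resample:
        scale = np.asarray(volume.spacing_mm)
        volume = resample_to_isotropic(volume)
        bbox = BBox3D(center=tuple(np.asarray(bbox.center) * scale),
                      size=tuple(np.maximum(np.asarray(bbox.size) * scale,
                                            1e-9)),
                      frame=VOXEL_ABSOLUTE)
    volume = window_and_normalize(volume)
    roi_s, box_s = crop_centered_roi(volume, bbox, crop_small)
    roi_l, box_l = crop_centered_roi(volume, bbox, crop_large)
    return PreparedCase(case_id=case_id, roi_small=roi_s, roi_large=roi_l,
                        bbox_small=box_s, bbox_large=box_l,
                        ehr_record=dict(ehr_record), label=int(label))


def make_roi_sample(case: PreparedCase, state: EHREncoderState) -> ROISample:
    return ROISample(roi_small=case.roi_small, roi_large=case.roi_large,
                     bbox_small=case.bbox_small, bbox_large=case.bbox_large,
                     ehr_vec=encode_ehr(case.ehr_record, state),
                     label=case.label)


def prepare_manifest(manifest: pd.DataFrame,
                     crop_small: Sequence[int] = CROP_SMALL,
                     crop_large: Sequence[int] = CROP_LARGE
                     ) -> list[PreparedCase]:
    """Run the imaging pipeline over every row of a dataset manifest."""
    reserved = {"case_id", "label", "cx", "cy", "cz", "w", "h", "d",
                "frame", "path"}
    ehr_cols = [c for c in manifest.columns if c not in reserved]
    cases = []
    for row in manifest.to_dict("records"):
        volume = load_nifti(row["path"])
        bbox = BBox3D(center=(row["cx"], row["cy"], row["cz"]),
                      size=(row["w"], row["h"], row["d"]),
                      frame=VOXEL_ABSOLUTE)
        cases.append(prepare_case(volume, bbox,
                                  {c: row[c] for c in ehr_cols},
                                  int(row["label"]),
                                  case_id=str(row["case_id"]),
                                  crop_small=crop_small,
                                  crop_large=crop_large))
    return cases


def save_cache(cases: Sequence[PreparedCase], out_dir: str | Path) -> None:
    """Persist prepared crops as NIfTI plus a JSON sidecar per case."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    eye = np.eye(4)
    for case in cases:
        for tag, grid in (("small", case.roi_small), ("large", case.roi_large)):
            nib.save(nib.Nifti1Image(grid.astype(np.float32), eye),
                     str(out_dir / f"{case.case_id}_{tag}.nii.gz"))
        box_s, box_l = case.bbox_small, case.bbox_large
        sidecar = {"case_id": case.case_id, "label": case.label,
                   "ehr_record": case.ehr_record,
                   "bbox_small": {"center": box_s.center, "size": box_s.size},
                   "bbox_large": {"center": box_l.center, "size": box_l.size}}
        (out_dir / f"{case.case_id}.json").write_text(json.dumps(sidecar))


def load_cache(cache_dir: str | Path) -> list[PreparedCase]:
    import nibabel as nib

    cache_dir = Path(cache_dir)
    cases = []
    for sidecar_path in sorted(cache_dir.glob("*.json")):
        meta = json.loads(sidecar_path.read_text())
        cid = meta["case_id"]
        grids = {}
        for tag in ("small", "large"):
            img = nib.load(str(cache_dir / f"{cid}_{tag}.nii.gz"))
            grids[tag] = np.asanyarray(img.dataobj).astype(np.float64)
        cases.append(PreparedCase(
            case_id=cid, roi_small=grids["small"], roi_large=grids["large"],
            bbox_small=BBox3D(center=tuple(meta["bbox_small"]["center"]),
                              size=tuple(meta["bbox_small"]["size"]),
                              frame=CROP_RELATIVE),
            bbox_large=BBox3D(center=tuple(meta["bbox_large"]["center"]),
                              size=tuple(meta["bbox_large"]["size"]),
                              frame=CROP_RELATIVE),
            ehr_record=meta["ehr_record"], label=int(meta["label"])))
    return cases
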