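"""Imaging pipeline and clinical-record encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cmmfnet as cm
from cmmfnet.preprocess import relative_to_absolute
from cmmfnet.types import BBox3D, CROP_RELATIVE, CTVolume


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def test_resample_preserves_constants_and_doubles_shape():
    vol = CTVolume(np.full((64, 64, 64), -500.0), spacing_mm=(2, 2, 2))
    out = cm.resample_to_isotropic(vol)
    assert out.shape == (128, 128, 128)
    assert out.spacing_mm == (1.0, 1.0, 1.0)
    np.testing.assert_allclose(out.voxels, -500.0)


def test_resample_shape_arithmetic_anisotropic():
    vol = CTVolume(np.zeros((512, 512, 40)), spacing_mm=(0.7, 0.7, 2.5))
    out = cm.resample_to_isotropic(vol)
    assert out.shape == (round(512 * 0.7), round(512 * 0.7), 100)


def test_resample_reproduces_linear_ramp():
    """Trilinear interpolation is exact on a linear intensity ramp."""
    x = np.arange(32, dtype=float)
    vol = CTVolume(np.broadcast_to(x[:, None, None] * 10 - 800,
                                   (32, 16, 16)).copy(),
                   spacing_mm=(2.0, 1.0, 1.0))
    out = cm.resample_to_isotropic(vol)
    assert out.shape == (64, 16, 16)
    # interior output index i sits at input coordinate i/2
    interior = np.arange(62)
    np.testing.assert_allclose(out.voxels[interior, 0, 0],
                               interior / 2 * 10 - 800, atol=1e-4)


def test_resample_rejects_bad_spacing():
    vol = CTVolume(np.zeros((4, 4, 4)), spacing_mm=(1, 1, 1))
    with pytest.raises(ValueError):
        cm.resample_to_isotropic(vol, target_spacing_mm=(0.0, 1.0, 1.0))


# --------------------------------------------------------------------------
# windowing
# --------------------------------------------------------------------------

@pytest.mark.parametrize("hu,expected", [(-2000.0, 0.0), (-1000.0, 0.0),
                                         (400.0, 1.0), (700.0, 1.0),
                                         (-300.0, 0.5)])
def test_window_maps_hu_to_unit_interval(hu, expected):
    vol = CTVolume(np.full((2, 2, 2), hu), spacing_mm=(1, 1, 1))
    assert cm.window_and_normalize(vol).voxels[0, 0, 0] == pytest.approx(expected)


def test_window_rejects_non_finite():
    vol = CTVolume(np.full((2, 2, 2), np.nan), spacing_mm=(1, 1, 1))
    with pytest.raises(ValueError):
        cm.window_and_normalize(vol)


# --------------------------------------------------------------------------
# cropping
# --------------------------------------------------------------------------

def _unit_volume(shape=(64, 64, 64), fill=0.7):
    return CTVolume(np.full(shape, fill), spacing_mm=(1, 1, 1))


def test_crop_centered_box_is_relative_half():
    bbox = BBox3D(center=(32, 32, 32), size=(8, 8, 8))
    _, rel = cm.crop_centered_roi(_unit_volume(), bbox, (32, 32, 32))
    assert rel.center == (0.5, 0.5, 0.5)
    assert rel.size == (0.25, 0.25, 0.25)
    assert rel.frame == CROP_RELATIVE


def test_crop_near_face_pads_with_air():
    """A bbox 4 voxels from the x=0 face cropped to 32^3: the left 12
    planes are padding (post-window floor 0) and centring stays exact."""
    vol = _unit_volume()
    bbox = BBox3D(center=(4, 32, 32), size=(6, 6, 6))
    crop, rel = cm.crop_centered_roi(vol, bbox, (32, 32, 32))
    np.testing.assert_allclose(crop[:12], 0.0)
    assert crop[12:].min() == pytest.approx(0.7)
    assert rel.center[0] == pytest.approx(0.5)


def test_crop_rejects_center_outside_and_huge_crops():
    vol = _unit_volume((16, 16, 16))
    with pytest.raises(ValueError):
        cm.crop_centered_roi(vol, BBox3D(center=(20, 8, 8), size=(2, 2, 2)),
                             (8, 8, 8))
    with pytest.raises(ValueError):
        cm.crop_centered_roi(vol, BBox3D(center=(8, 8, 8), size=(2, 2, 2)),
                             (80, 8, 8))


@settings(derandomize=True, max_examples=50)
@given(cx=st.floats(20, 40), cy=st.floats(20, 40), cz=st.floats(20, 40),
       w=st.floats(2, 10), h=st.floats(2, 10), d=st.floats(2, 10))
def test_relative_round_trip_recovers_voxel_box(cx, cy, cz, w, h, d):
    """abs -> crop-relative -> abs recovers the box within half a voxel."""
    vol = _unit_volume()
    bbox = BBox3D(center=(cx, cy, cz), size=(w, h, d))
    crop_shape = (32, 32, 32)
    _, rel = cm.crop_centered_roi(vol, bbox, crop_shape)
    origin = np.floor(np.asarray(bbox.center) + 0.5).astype(int) \
        - np.asarray(crop_shape) // 2
    back = relative_to_absolute(rel, origin, crop_shape)
    np.testing.assert_allclose(back.center, bbox.center, atol=0.5)
    np.testing.assert_allclose(back.size, bbox.size, atol=0.5)


# --------------------------------------------------------------------------
# flips
# --------------------------------------------------------------------------

def test_flip_reflects_center_keeps_size():
    grid = np.zeros((8, 8, 8))
    bbox = BBox3D(center=(0.3, 0.5, 0.5), size=(0.2, 0.2, 0.2),
                  frame=CROP_RELATIVE)
    _, flipped = cm.flip_with_bbox(grid, bbox, axis=0)
    assert flipped.center[0] == pytest.approx(0.7)
    assert flipped.size == bbox.size


def test_flip_is_involution(rng):
    grid = rng.random((8, 8, 8))
    bbox = BBox3D(center=(0.3, 0.6, 0.4), size=(0.1, 0.2, 0.3),
                  frame=CROP_RELATIVE)
    g1, b1 = cm.flip_with_bbox(grid, bbox, axis=1)
    g2, b2 = cm.flip_with_bbox(g1, b1, axis=1)
    np.testing.assert_array_equal(g2, grid)
    assert b2.center == bbox.center


def test_flip_mirrors_intensity_peak_with_box(rng):
    """The grid's argmax mirrors exactly in step with the box center."""
    grid = rng.random((16, 16, 16))
    peak = np.unravel_index(np.argmax(grid), grid.shape)
    bbox = BBox3D(center=tuple((np.asarray(peak) + 0.5) / 16),
                  size=(0.1, 0.1, 0.1), frame=CROP_RELATIVE)
    for axis in range(3):
        g, b = cm.flip_with_bbox(grid, bbox, axis)
        new_peak = np.unravel_index(np.argmax(g), g.shape)
        assert (new_peak[axis] + 0.5) / 16 == pytest.approx(b.center[axis])


def test_flip_rejects_bad_axis():
    bbox = BBox3D(center=(0.5, 0.5, 0.5), size=(0.1, 0.1, 0.1),
                  frame=CROP_RELATIVE)
    with pytest.raises(ValueError):
        cm.flip_with_bbox(np.zeros((4, 4, 4)), bbox, axis=3)


# --------------------------------------------------------------------------
# EHR encoding
# --------------------------------------------------------------------------

def test_numeric_standardization_uses_population_convention():
    df = pd.DataFrame({"age": [50.0, 60.0, 70.0]})
    state = cm.fit_ehr_encoder(df)
    assert state.numeric_mean["age"] == 60.0
    assert state.numeric_sd["age"] == pytest.approx(np.sqrt(200.0 / 3.0))
    vec = cm.encode_ehr({"age": 60.0}, state)
    assert vec.values[0] == pytest.approx(0.0)


def test_categorical_vocabulary_one_hot():
    df = pd.DataFrame({"sex": ["M", "F", "M"]})
    state = cm.fit_ehr_encoder(df)
    assert state.feature_names == ["sex=F", "sex=M"]
    np.testing.assert_array_equal(cm.encode_ehr({"sex": "M"}, state).values,
                                  [0.0, 1.0])


def test_fitting_split_z_scores_have_zero_mean_unit_variance():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"a": rng.normal(5, 2, 40), "b": rng.normal(-1, 9, 40),
                       "cat": rng.choice(["x", "y", "z"], 40)})
    state = cm.fit_ehr_encoder(df)
    enc = cm.encode_ehr_table(df, state)
    np.testing.assert_allclose(enc[:, :2].mean(axis=0), 0.0, atol=1e-6)
    np.testing.assert_allclose(enc[:, :2].var(axis=0), 1.0, atol=1e-6)


def test_refit_is_deterministic():
    df = pd.DataFrame({"a": [1.0, 2.0, 4.0], "c": ["u", "v", "u"]})
    s1, s2 = cm.fit_ehr_encoder(df), cm.fit_ehr_encoder(df)
    assert s1 == s2


def test_unseen_category_encodes_to_zeros_with_warning():
    state = cm.fit_ehr_encoder(pd.DataFrame({"c": ["u", "v"]}))
    with pytest.warns(UserWarning, match="unseen"):
        vec = cm.encode_ehr({"c": "w"}, state)
    np.testing.assert_array_equal(vec.values, [0.0, 0.0])


def test_encoder_error_paths():
    with pytest.raises(ValueError, match="flat"):
        cm.fit_ehr_encoder(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))
    state = cm.fit_ehr_encoder(pd.DataFrame({"a": [1.0, 2.0]}))
    with pytest.raises(ValueError, match="missing"):
        cm.encode_ehr({}, state)


# --------------------------------------------------------------------------
# composed pipeline
# --------------------------------------------------------------------------

def test_pipeline_produces_exact_shapes_and_unit_range():
    """resample -> window -> dual-scale crop on an anisotropic phantom."""
    spec = cm.PhantomSpec(volume_shape_vox=(48, 48, 32),
                          spacing_mm=(1.0, 1.0, 2.0), seed=6)
    case = cm.sample_case(spec, 1, np.random.default_rng(6))
    prep = cm.prepare_case(case.volume, case.bbox, case.ehr, case.label,
                           crop_small=(32, 32, 32), crop_large=(64, 64, 32))
    assert prep.roi_small.shape == (32, 32, 32)
    assert prep.roi_large.shape == (64, 64, 32)
    for grid in (prep.roi_small, prep.roi_large):
        assert 0.0 <= grid.min() and grid.max() <= 1.0
    for box in (prep.bbox_small, prep.bbox_large):
        assert box.frame == CROP_RELATIVE


def test_cache_round_trip(tmp_path, small_cohort_30):
    cases = small_cohort_30[:3]
    cm.save_cache(cases, tmp_path / "cache")
    loaded = cm.load_cache(tmp_path / "cache")
    assert [c.case_id for c in loaded] == [c.case_id for c in cases]
    np.testing.assert_allclose(loaded[0].roi_small, cases[0].roi_small,
                               atol=1e-6)
    assert loaded[0].ehr_record.keys() == cases[0].ehr_record.keys()
    for key, val in cases[0].ehr_record.items():
        if isinstance(val, float):
            assert loaded[0].ehr_record[key] == pytest.approx(val)
        else:
            assert loaded[0].ehr_record[key] == val
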