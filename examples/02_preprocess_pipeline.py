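"""Run the CT preparation pipeline on one phantom.

Resampling to 1 mm isotropic voxels, windowing to [-1000, 400] HU, dual-
scale lesion-centred cropping with crop-relative boxes, and a flip
augmentation that mirrors grid and box together.
"""

import numpy as np

import cmmfnet as cm

spec = cm.PhantomSpec(volume_shape_vox=(48, 48, 32), spacing_mm=(1.0, 1.0, 2.0),
                      seed=3)
case = cm.sample_case(spec, 2, np.random.default_rng(3))
print(f"raw volume {case.volume.shape} at spacing {case.volume.spacing_mm} mm")

iso = cm.resample_to_isotropic(case.volume)
print(f"resampled  {iso.shape} at spacing {iso.spacing_mm} mm")

prep = cm.prepare_case(case.volume, case.bbox, case.ehr, case.label,
                       crop_small=(32, 32, 32), crop_large=(64, 64, 32))
print(f"crops      {prep.roi_small.shape} and {prep.roi_large.shape}, "
      f"intensities in [{prep.roi_small.min():.2f}, {prep.roi_small.max():.2f}]")
print(f"relative box (small crop): center "
      f"{tuple(round(c, 3) for c in prep.bbox_small.center)}, size "
      f"{tuple(round(s, 3) for s in prep.bbox_small.size)}")

# lesion-centred crops put the box center at 0.5; use an off-center box to
# show the reflection
offset_box = cm.BBox3D(center=(0.3, 0.5, 0.5), size=(0.2, 0.2, 0.2),
                       frame="crop-relative")
flipped, fbox = cm.flip_with_bbox(prep.roi_small, offset_box, axis=0)
print(f"after an axis-0 flip the box center x moves "
      f"{offset_box.center[0]:.3f} -> {fbox.center[0]:.3f} "
      f"(reflection about 0.5); flipping again restores the grid exactly: "
      f"{np.array_equal(cm.flip_with_bbox(flipped, fbox, 0)[0], prep.roi_small)}")

# The windowed crop lives in [0, 1] (0 = air at -1000 HU, 1 = +400 HU), the
# box is expressed as fractions of the crop extent, and augmentation keeps
# box and image geometry consistent.
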