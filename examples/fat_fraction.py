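"""Quantify marrow fat fraction from a Dixon water/fat pair.

Simulates a baseline study with marrow FF = 56% and a follow-up at 40%
(the signature of increasing diffuse infiltration despite stable focal
burden), computes the FF maps and ROI means, and reports the percentage
change.
"""

from tdvpipe import compute_ff_map, percentage_change, roi_mean
from tdvpipe.ff_quant import DIXON_ROI_AREA_BOUNDS_MM2, RectRoi
from tdvpipe.synthdata import PhantomSpec, generate_phantom

roi = RectRoi(plane="coronal", slice_index=32, corner=(27, 40),
              extent=(10, 12))
means = {}
for label, ff_true in (("baseline", 56.0), ("follow-up", 40.0)):
    spec = PhantomSpec(pattern="normal", lesions=[],
                       marrow_ff_percent=ff_true)
    study = generate_phantom(spec)
    ffmap = compute_ff_map(study.dixon_water, study.dixon_fat,
                           spec.voxel_spacing)
    means[label] = roi_mean(ffmap, roi, area_bounds=DIXON_ROI_AREA_BOUNDS_MM2)
    print(f"{label:9s}: ROI mean FF = {means[label]:.1f}% "
          f"(true {ff_true:.0f}%)")

change = percentage_change(means["baseline"], means["follow-up"])
print(f"percentage change = {change:.1f}%")
# Falling marrow FF means fat is being displaced by cellular infiltrate;
# rising FF after therapy signals marrow recovery.
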