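"""Area-weighted VOI value from per-slice ROI means (ΣAV/ΣA).

A 3-slice DDC map with slices of different tumor area illustrates why
the VOI value is not the plain mean of the slice means: larger slices
carry proportionally more weight.
"""

import numpy as np

from mbdwi import extract_roi_means, voi_weighted_mean

# toy 4x4x3 DDC map (10^-3 mm^2/s) with a growing tumor cross-section
ddc_map = np.full((4, 4, 3), np.nan)
mask = np.zeros((4, 4, 3), bool)
mask[1:2, 1:2, 0] = True            # 1 voxel
mask[1:3, 1:3, 1] = True            # 4 voxels
mask[0:3, 0:3, 2] = True            # 9 voxels
ddc_map[:, :, 0] = 0.70
ddc_map[:, :, 1] = 0.90
ddc_map[:, :, 2] = 1.10

slices = extract_roi_means(ddc_map, mask, voxel_area=2.0)  # 2 mm^2 voxels
for s in slices:
    print(f"slice {s.slice_index}: area {s.area:.0f} mm^2, mean DDC {s.mean_value:.2f}")

summary = voi_weighted_mean(slices, patient_id="P001", parameter="ddc")
print(f"\nVOI DDC = {summary.value:.4f} (area-weighted over {summary.n_slices} slices)")
print(f"plain slice-mean average would be {np.mean([s.mean_value for s in slices]):.4f}")
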