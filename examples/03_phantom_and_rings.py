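"""Build a lesioned brain phantom and measure the perilesional gradient.

Generates a label volume with periventricular and deep WMH blobs, paints
the programmed interstitial-fluid gradient (quadratic decay over 6 mm),
builds the 2 mm distance rings with CSF exclusion, and extracts ring means
of the ground-truth GMT2 map -- showing the penumbra profile the downstream
statistics are designed to detect.
"""

from wmh_penumbra.phantom import LABELS, make_label_volume, paint_ground_truth
from wmh_penumbra.rois import classify_wmh, extract_roi_means, make_rings, wmh_volume_ml

lv = make_label_volume((48, 48, 48), (1, 1, 1), n_deep_wmh=1, n_pv_wmh=1, seed=7)
gt = paint_ground_truth(lv, group="stroke", seed=7)

cls = classify_wmh(lv.mask("wmh"), lv.mask("ventricular_csf"))
print(f"WMH components: {int((cls == 1).any())} periventricular, "
      f"{int((cls == 2).any())} deep; lesion volume "
      f"{wmh_volume_ml(lv.mask('wmh'), lv.voxel_size_mm):.3f} mL")

rings = make_rings(
    lv.mask("wmh"), lv.mask("nawm"),
    csf_mask=lv.mask("ventricular_csf") | lv.mask("sulcal_csf"),
    voxel_size_mm=lv.voxel_size_mm,
)
table = extract_roi_means(rings, {"GMT2": gt.ie_t2_true, "MD": gt.md_true})
pivot = table.pivot(index="distance_level", columns="metric", values="value")
print(pivot.reindex(["WMH", "2", "4", "6", "8", "10"]).round(4))
# GMT2 (ms) and MD (mm^2/s) are highest in the WMH and decay quadratically
# back to the NAWM baseline (80 ms / 0.75e-3) within ~6 mm: the penumbra.
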