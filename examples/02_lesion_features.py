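"""Extract the eight lesion features from one synthetic patient.

Shows the per-patient feature vector that, together with the four clinical
features (age, gender, CIS type, EDSS), forms one row of the design matrix.
"""

from cispredict import CohortConfig, encode_clinical, extract_all, generate_cohort

cfg = CohortConfig(
    n_converters=1, n_nonconverters=1, seed=3,
    native_shape=(64, 64, 24), native_voxel_mm=(3.0, 3.0, 5.0),
    template_shape=(45, 54, 45), template_voxel_mm=(4.0, 4.0, 4.0),
)
rec = generate_cohort(cfg)[0]
fs = extract_all(rec)

print(f"patient {rec.id} ({'converter' if rec.label == 1 else 'non-converter'})")
print(f"  lesion count            : {fs.lesion_count}   (18-connected components)")
print(f"  lesion load             : {fs.lesion_load_voxels} voxels")
print(f"  mean PD / T2 intensity  : {fs.mean_pd_intensity:.1f} / {fs.mean_t2_intensity:.1f}"
      "   (lesions are hyperintense over ~100 background)")
print(f"  mean dist. to centre    : {fs.mean_dist_to_center_mm:.1f} mm (template space)")
print(f"  central 1 cm^3 cube     : {fs.central_cube_presence}   (1 = lesion near brain centre)")
print(f"  min centroid-axis dist. : {fs.min_centroid_axis_dist_mm:.1f} mm "
      "(in-plane distance to the vertical axis)")
print(f"  size profile            : {fs.size_profile}   (small 1-15 / medium 16-36 / large 37+)")
print(f"  clinical sub-vector     : {encode_clinical(rec)}  (age, gender, CIS type, EDSS)")
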