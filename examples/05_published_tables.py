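"""Recompute every derived summary of the packaged per-patient tables:
cluster counts under the three registration schemes, signed-rank tests,
voxel ratios, and misregistration percentages.
"""

from surequant.stats_tables import (
    load_table,
    summarize_table1,
    summarize_table2,
    summarize_table3,
    summarize_table4,
    table1_wilcoxon,
)

s1 = summarize_table1(load_table(1))
print("cluster counts: sBR =", s1["sum_sbr"], " aBR-MNI =", s1["sum_abr_mni"],
      " aBR-JHU =", s1["sum_abr_jhu"])
print("subjects with >=1 sBR cluster:", s1["subjects_with_sbr_clusters"], "of 20")
print("sBR clusters recovered by aBR: "
      f"{s1['recovery_pct_mni']}% (MNI), {s1['recovery_pct_jhu']}% (JHU)")

for name, res in table1_wilcoxon().items():
    print(f"signed-rank {name}: W = {res.W:.0f}, N = {res.N}, "
          f"one-tailed p = {res.p_one_tailed:.2g} ({res.method})")

s2 = summarize_table2(load_table(2))
print("abnormal-voxel ratio, aBR/sBR, over the 9 sBR-positive subjects: "
      f"{s2['ratio_mean_mni']}% (MNI), {s2['ratio_mean_jhu']}% (JHU)")

s3 = summarize_table3(load_table(3))
print(f"GM/CSF misregistered onto template WM: {s3['mean_pct_mni']}% (MNI), "
      f"{s3['mean_pct_jhu']}% (JHU); per-row recomputation matches printed: "
      f"{s3['recomputation_matches_printed']}")

s4 = summarize_table4(load_table(4))
print(f"cluster voxels inside misregistration mask: {s4['mean_pct_mni']}% (MNI), "
      f"{s4['mean_pct_jhu']}% (JHU); sBR column identically zero: {s4['sbr_all_zero']}")

# Atlas-based analyses find ~4x the clusters and ~4x the abnormal voxels of
# the subject-based analysis, and 40-51% of those cluster voxels coincide
# with tissue the registration misplaced onto template white matter.
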