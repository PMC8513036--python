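# Synthetic default isomer catalog: 102 serum-AGP N-glycan isomers.
# Baseline abundances, RSDs and retention times are synthetic placeholders,
# not measured values. rsd_pct is the isomer-specific residual CV; the
# generator adds a shared per-glycan factor and a per-sample scale on top.
composition,isomer_index,rt_min,baseline_mean_pct,rsd_pct
N4H5S,1,43.62,1.8,30
N4H5S,2,43.87,1.2,30
N4H5SF,1,44.12,0.6,35
N4H5SF,2,44.36,0.48,35
N4H5SF,3,44.61,0.38,35
N4H5SF,4,44.86,0.3,35
N4H5SF,5,45.1,0.24,35
N4H5SF2,1,45.35,0.3,45
N4H5SF2,2,45.6,0.2,45
N5H6S,1,45.84,0.675,30
N5H6S,2,46.09,0.45,30
N5H6S,3,46.34,0.375,30
N5H6SF,1,46.58,0.36,40
N5H6SF,2,46.83,0.24,40
N5H6SF,3,47.08,0.2,40
N4H5S2,1,61.6,5.4,25
N4H5S2,2,62.01,3.6,25
N4H5S2,3,62.42,3.0,25
N4H5S2F,1,62.83,1.125,35
N4H5S2F,2,63.24,0.75,35
N4H5S2F,3,63.65,0.625,35
N4H5S2F2,1,64.06,0.36,45
N4H5S2F2,2,64.47,0.24,45
N5H6S2,1,64.88,2.6,40
N5H6S2,2,65.28,2.1,40
N5H6S2,3,65.69,1.7,40
N5H6S2,4,66.1,1.4,20
N5H6S2,5,66.51,1.2,20
N5H6S2,6,66.92,1.0,40
N5H6S2F,1,67.33,1.05,35
N5H6S2F,2,67.74,0.84,35
N5H6S2F,3,68.15,0.66,35
N5H6S2F,4,68.55,0.45,35
N5H6S2F2,1,68.96,0.36,45
N5H6S2F2,2,69.37,0.24,45
N5H6S2F2,3,69.78,0.2,45
N6H7S2,1,70.19,1.3,40
N6H7S2,2,70.6,1.05,40
N6H7S2,3,71.01,0.85,20
N6H7S2,4,71.42,0.7,20
N6H7S2,5,71.83,0.6,20
N6H7S2,6,72.23,0.5,40
N6H7S2F,1,72.64,0.875,40
N6H7S2F,2,73.05,0.7,20
N6H7S2F,3,73.46,0.55,20
N6H7S2F,4,73.87,0.375,40
N6H7S2F2,1,74.28,0.315,40
N6H7S2F2,2,74.69,0.21,40
N6H7S2F2,3,75.1,0.175,40
N5H6S3,1,83.77,3.6,30
N5H6S3,2,84.32,3.06,30
N5H6S3,3,84.87,2.7,30
N5H6S3,4,85.42,2.34,30
N5H6S3,5,85.97,1.98,30
N5H6S3,6,86.52,1.62,30
N5H6S3,7,87.07,1.44,30
N5H6S3,8,87.62,1.26,30
N5H6S3F,1,88.17,1.4,20
N5H6S3F,2,88.72,1.12,20
N5H6S3F,3,89.27,0.88,40
N5H6S3F,4,89.81,0.6,40
N5H6S3F2,1,90.36,0.54,40
N5H6S3F2,2,90.91,0.36,40
N5H6S3F2,3,91.46,0.3,40
N5H6S3F3,1,92.01,0.3,45
N5H6S3F3,2,92.56,0.2,45
N6H7S3,1,93.11,3.12,30
N6H7S3,2,93.66,2.52,30
N6H7S3,3,94.21,2.04,30
N6H7S3,4,94.76,1.68,30
N6H7S3,5,95.3,1.44,30
N6H7S3,6,95.85,1.2,30
N6H7S3F,1,96.4,1.05,40
N6H7S3F,2,96.95,0.84,40
N6H7S3F,3,97.5,0.66,40
N6H7S3F,4,98.05,0.45,40
N6H7S3F2,1,98.6,0.405,45
N6H7S3F2,2,99.15,0.27,45
N6H7S3F2,3,99.7,0.225,45
N6H7S4,1,100.25,2.4,30
N6H7S4,2,100.8,1.92,30
N6H7S4,3,101.34,1.52,30
N6H7S4,4,101.89,1.2,30
N6H7S4,5,102.44,0.96,30
N6H7S4F,1,102.99,0.875,40
N6H7S4F,2,103.54,0.7,40
N6H7S4F,3,104.09,0.55,40
N6H7S4F,4,104.64,0.375,40
N6H7S4F2,1,105.19,0.36,45
N6H7S4F2,2,105.74,0.24,45
N6H7S4F2,3,106.29,0.2,45
N7H8S3,1,106.83,0.675,35
N7H8S3,2,107.38,0.45,35
N7H8S3,3,107.93,0.375,35
N7H8S4,1,108.48,0.875,35
N7H8S4,2,109.03,0.7,35
N7H8S4,3,109.58,0.55,35
N7H8S4,4,110.13,0.375,35
N7H8S4F,1,110.68,0.42,45
N7H8S4F,2,111.23,0.28,45
N7H8S4F2,1,111.78,0.24,45
N7H8S4F2,2,112.33,0.16,45
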