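id,residual_A,residual_A_se,residual_B,residual_B_se,ic50_A,ic50_A_censor,ic50_A_se,ic50_B,ic50_B_censor,ic50_B_se
B1,82.62,5.03,35.53,6.05,26.923,exact,4.160,1.441,exact,0.149
B2,53.15,1.58,23.59,0.96,13.728,exact,1.531,0.626,exact,0.296
B3,58.32,0.84,0,,14.267,exact,0.203,0.261,exact,0.016
B4,78.25,4.32,16.24,6.49,29.376,exact,2.708,0.233,exact,0.110
B5,89.21,4.47,0,,40,greater_than,,0.224,exact,0.082
B6,92.00,2.93,41.33,4.90,40,greater_than,,6.550,exact,1.344
B7,58.43,4.48,0,,12.597,exact,0.898,0.149,exact,0.006
B8,92.45,0.49,64.36,1.50,40,greater_than,,17.880,exact,0.268
B9,69.09,1.54,0,,23.966,exact,1.443,0.236,exact,0.017
B10,76.67,3.22,0,,33.821,exact,6.888,0.067,exact,0.005
B11,81.27,2.92,41.20,0.12,40,greater_than,,5.784,exact,2.387
B12,86.70,2.68,75.44,3.60,40,greater_than,,37.559,exact,1.882
B13,99.12,1.24,1.39,3.27,40,greater_than,,0.255,exact,0.016
B14,91.23,6.20,51.85,1.31,40,greater_than,,11.347,exact,0.331
B15,75.88,3.10,0,,34.512,exact,3.544,0.120,exact,0.010
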