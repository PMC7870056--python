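# Male transition probabilities per 1-year cycle, with incident counts (ic)
# and incident rates (ir, per 1,000 persons per year), by 5-year age group,
# 2016 index year, Korean national claims data.
# Age-group labels use ASCII hyphens. The 45-49 row is printed as "45-59" in
# the original source table; by position (between 40-44 and 50-54) it is
# 45-49 and is corrected here.
age_group,ic,ir,di_ci,di_dthdm,di_dthoth,dep_ci,dep_dthdm,dep_dthoth,ci_dthdm,ci_dthoth,cep_dthdm,cep_dthoth
30-34,6736,3.7,0.171,0.004,0.007,0.106,0.002,0.001,0.001,0.004,0.010,0.005
35-39,10909,5.4,0.121,0.000,0.014,0.105,0.001,0.006,0.001,0.006,0.002,0.008
40-44,18310,8.5,0.113,0.001,0.017,0.093,0.002,0.006,0.001,0.010,0.001,0.008
45-49,25951,11.5,0.116,0.001,0.017,0.098,0.001,0.008,0.001,0.010,0.002,0.009
50-54,30739,14.5,0.113,0.002,0.025,0.102,0.001,0.012,0.001,0.010,0.003,0.011
55-59,34156,16.8,0.117,0.001,0.027,0.103,0.002,0.017,0.002,0.010,0.004,0.014
60-64,27605,19.0,0.189,0.003,0.047,0.152,0.002,0.023,0.001,0.015,0.004,0.017
65-69,20110,19.2,0.175,0.003,0.070,0.150,0.003,0.043,0.009,0.024,0.007,0.031
70-74,15486,19.5,0.140,0.003,0.115,0.139,0.009,0.058,0.009,0.049,0.012,0.050
75-79,11132,19.4,0.127,0.002,0.160,0.131,0.010,0.088,0.003,0.059,0.015,0.067
80-84,5988,20.0,0.078,0.010,0.240,0.090,0.032,0.129,0.008,0.108,0.024,0.117
85+,2868,20.4,0.043,0.015,0.265,0.059,0.033,0.144,0.028,0.205,0.037,0.122
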