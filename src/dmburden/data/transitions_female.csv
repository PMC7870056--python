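# Female transition probabilities per 1-year cycle, with incident counts (ic)
# and incident rates (ir, per 1,000 persons per year), by 5-year age group,
# 2016 index year, Korean national claims data.
# Age-group labels use ASCII hyphens. The 45-49 row is printed as "45-59" in
# the original source table; by position (between 40-44 and 50-54) it is
# 45-49 and is corrected here.
age_group,ic,ir,di_ci,di_dthdm,di_dthoth,dep_ci,dep_dthdm,dep_dthoth,ci_dthdm,ci_dthoth,cep_dthdm,cep_dthoth
30-34,3940,2.2,0.157,0.005,0.011,0.123,0.004,0.003,0.001,0.001,0.013,0.007
35-39,4671,2.4,0.134,0.004,0.039,0.121,0.000,0.003,0.001,0.001,0.003,0.018
40-44,6990,3.3,0.150,0.002,0.039,0.117,0.000,0.003,0.001,0.002,0.003,0.018
45-49,11690,5.3,0.164,0.002,0.039,0.124,0.000,0.005,0.001,0.003,0.005,0.018
50-54,17612,8.6,0.130,0.003,0.040,0.121,0.000,0.006,0.001,0.005,0.004,0.018
55-59,22627,11.1,0.143,0.002,0.040,0.127,0.000,0.008,0.001,0.005,0.005,0.018
60-64,21202,14.0,0.185,0.004,0.055,0.175,0.002,0.010,0.001,0.005,0.005,0.020
65-69,17810,15.7,0.201,0.002,0.064,0.170,0.002,0.016,0.002,0.014,0.006,0.027
70-74,16503,17.0,0.196,0.002,0.092,0.170,0.005,0.031,0.002,0.019,0.008,0.032
75-79,14176,17.0,0.152,0.001,0.092,0.154,0.008,0.052,0.006,0.047,0.007,0.035
80-84,9409,16.6,0.136,0.006,0.141,0.113,0.015,0.093,0.003,0.073,0.008,0.042
85+,6245,15.0,0.094,0.007,0.141,0.058,0.037,0.102,0.016,0.109,0.015,0.050
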