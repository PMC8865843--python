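curve,frequency_hz,sensitivity
RA,5.0,0.00015
RA,5.45,0.00029
RA,5.94,0.00055
RA,6.47,0.00099
RA,7.05,0.00176
RA,7.69,0.00305
RA,8.38,0.00513
RA,9.13,0.0084
RA,9.95,0.01346
RA,10.84,0.02101
RA,11.82,0.03215
RA,12.88,0.04783
RA,14.04,0.06954
RA,15.3,0.09855
RA,16.67,0.13621
RA,18.17,0.18397
RA,19.8,0.24227
RA,21.58,0.31151
RA,23.52,0.39084
RA,25.63,0.47832
RA,27.93,0.5713
RA,30.44,0.66603
RA,33.18,0.75783
RA,36.16,0.8412
RA,39.41,0.91122
RA,42.95,0.96317
RA,46.8,0.99345
RA,51.01,1.0
RA,55.59,0.98226
RA,60.58,0.94154
RA,66.03,0.88059
RA,71.96,0.80377
RA,78.42,0.71596
RA,85.46,0.62235
RA,93.14,0.52783
RA,101.51,0.43684
RA,110.63,0.35281
RA,120.56,0.27812
RA,131.39,0.2139
RA,143.2,0.16051
RA,156.06,0.11757
RA,170.08,0.08402
RA,185.36,0.05859
RA,202.01,0.03988
RA,220.15,0.02649
RA,239.93,0.01716
RA,261.48,0.01085
RA,284.97,0.0067
RA,310.56,0.00403
RA,338.46,0.00237
RA,368.87,0.00136
RA,402.0,0.00076
RA,438.11,0.00041
RA,477.47,0.00022
RA,520.36,0.00011
RA,567.1,6e-05
RA,618.04,3e-05
RA,673.56,1e-05
RA,734.06,0.0
RA,800.0,0.0
PC,5.0,0.0
PC,5.45,0.0
PC,5.94,0.0
PC,6.47,0.0
PC,7.05,0.0
PC,7.69,0.0
PC,8.38,0.0
PC,9.13,0.0
PC,9.95,0.0
PC,10.84,0.0
PC,11.82,0.0
PC,12.88,0.0
PC,14.04,0.0
PC,15.3,0.0
PC,16.67,0.0
PC,18.17,0.0
PC,19.8,0.0
PC,21.58,0.0
PC,23.52,0.0
PC,25.63,0.0
PC,27.93,0.0
PC,30.44,0.0
PC,33.18,0.0
PC,36.16,0.0
PC,39.41,1e-05
PC,42.95,2e-05
PC,46.8,6e-05
PC,51.01,0.00014
PC,55.59,0.00034
PC,60.58,0.00079
PC,66.03,0.00174
PC,71.96,0.00365
PC,78.42,0.00733
PC,85.46,0.01406
PC,93.14,0.02576
PC,101.51,0.04505
PC,110.63,0.07523
PC,120.56,0.11991
PC,131.39,0.18253
PC,143.2,0.26537
PC,156.06,0.36824
PC,170.08,0.48795
PC,185.36,0.61736
PC,202.01,0.74575
PC,220.15,0.86011
PC,239.93,0.94724
PC,261.48,0.99603
PC,284.97,1.0
PC,310.56,0.95863
PC,338.46,0.87743
PC,368.87,0.76678
PC,402.0,0.63984
PC,438.11,0.50978
PC,477.47,0.38778
PC,520.36,0.28166
PC,567.1,0.19534
PC,618.04,0.12935
PC,673.56,0.08178
PC,734.06,0.04937
PC,800.0,0.02846
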