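23.180000
26.950000 13.240000
17.670000 1.900000 794.380000
59.930000 103.330000 58.940000 1.900000
1.900000 220.990000 173.560000 55.280000 75.240000
9.770000 1.900000 63.050000 583.550000 1.900000 313.560000
120.710000 23.030000 53.300000 56.770000 30.710000 6.750000 28.280000
13.900000 165.230000 496.130000 113.990000 141.490000 582.400000 49.120000 1.900000
96.490000 1.900000 27.100000 4.340000 62.730000 8.340000 3.310000 5.980000 12.260000
25.460000 15.580000 15.160000 1.900000 25.650000 39.700000 1.900000 2.410000 11.490000 329.090000
8.360000 141.400000 608.700000 2.310000 1.900000 465.580000 313.860000 22.730000 127.670000 19.570000 14.880000
141.880000 1.900000 65.410000 1.900000 6.180000 47.370000 1.900000 1.900000 11.970000 517.980000 537.530000 91.370000
6.370000 4.690000 15.200000 4.980000 70.800000 19.110000 2.670000 1.900000 48.160000 84.670000 216.060000 6.440000 90.820000
54.310000 23.640000 73.310000 13.430000 31.260000 137.290000 12.830000 1.900000 60.970000 20.630000 40.100000 50.100000 18.840000 17.310000
387.860000 6.040000 494.390000 69.020000 277.050000 54.110000 54.710000 125.930000 77.460000 47.700000 73.610000 105.790000 111.160000 64.290000 169.900000
480.720000 2.080000 238.460000 28.010000 179.970000 94.930000 14.820000 11.170000 44.780000 368.430000 126.400000 136.330000 528.170000 33.850000 128.220000 597.210000
1.900000 21.950000 10.680000 19.860000 33.600000 1.900000 1.900000 10.920000 7.080000 1.900000 32.440000 24.000000 21.710000 7.840000 4.210000 38.580000 9.990000
6.480000 1.900000 191.360000 21.210000 254.770000 38.820000 13.120000 3.210000 670.140000 25.010000 44.150000 51.170000 39.960000 465.580000 16.210000 64.920000 38.730000 26.250000
195.060000 7.640000 1.900000 1.900000 1.900000 19.000000 21.140000 2.530000 1.900000 1222.940000 91.670000 1.900000 387.540000 6.350000 8.230000 1.900000 204.540000 5.370000 1.900000

0.072000 0.019000 0.039000 0.019000 0.006000 0.025000 0.024000 0.056000 0.028000 0.088000 0.169000 0.023000 0.054000 0.061000 0.054000 0.072000 0.086000 0.029000 0.033000 0.043000
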