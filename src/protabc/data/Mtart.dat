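0.200000
0.200000 0.200000
1.000000 4.000000 500.000000
254.000000 36.000000 98.000000 11.000000
0.200000 154.000000 262.000000 0.200000 0.200000
0.200000 0.200000 183.000000 862.000000 0.200000 262.000000
200.000000 0.200000 121.000000 12.000000 81.000000 3.000000 44.000000
0.200000 41.000000 180.000000 0.200000 12.000000 314.000000 15.000000 0.200000
26.000000 2.000000 21.000000 7.000000 63.000000 11.000000 7.000000 3.000000 0.200000
4.000000 2.000000 13.000000 1.000000 79.000000 16.000000 2.000000 1.000000 6.000000 515.000000
0.200000 209.000000 467.000000 2.000000 0.200000 349.000000 106.000000 0.200000 0.200000 3.000000 4.000000
121.000000 5.000000 79.000000 0.200000 312.000000 67.000000 0.200000 56.000000 0.200000 515.000000 885.000000 106.000000
13.000000 5.000000 20.000000 0.200000 184.000000 0.200000 0.200000 1.000000 14.000000 118.000000 263.000000 11.000000 322.000000
49.000000 0.200000 17.000000 0.200000 0.200000 39.000000 8.000000 0.200000 1.000000 0.200000 12.000000 17.000000 5.000000 15.000000
673.000000 3.000000 398.000000 44.000000 664.000000 52.000000 31.000000 226.000000 11.000000 7.000000 8.000000 144.000000 112.000000 36.000000 87.000000
244.000000 0.200000 166.000000 0.200000 183.000000 44.000000 43.000000 0.200000 19.000000 204.000000 48.000000 70.000000 289.000000 14.000000 47.000000 660.000000
0.200000 0.200000 8.000000 0.200000 22.000000 7.000000 11.000000 2.000000 0.200000 0.200000 21.000000 16.000000 71.000000 54.000000 0.200000 2.000000 0.200000
1.000000 4.000000 251.000000 0.200000 72.000000 87.000000 8.000000 9.000000 191.000000 12.000000 20.000000 117.000000 71.000000 792.000000 18.000000 30.000000 46.000000 38.000000
340.000000 0.200000 23.000000 0.200000 350.000000 0.200000 14.000000 3.000000 0.200000 1855.000000 85.000000 26.000000 281.000000 52.000000 32.000000 61.000000 544.000000 0.200000 2.000000

0.054116 0.018227 0.039903 0.020160 0.009709 0.018781 0.024289 0.068183 0.024518 0.092638 0.148658 0.021718 0.061453 0.088668 0.041826 0.091030 0.049194 0.029786 0.039443 0.057700
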