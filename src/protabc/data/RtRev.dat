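34.000000
51.000000 35.000000
10.000000 30.000000 384.000000
439.000000 92.000000 128.000000 1.000000
32.000000 221.000000 236.000000 78.000000 70.000000
81.000000 10.000000 79.000000 542.000000 1.000000 372.000000
135.000000 41.000000 94.000000 61.000000 48.000000 18.000000 70.000000
30.000000 90.000000 320.000000 91.000000 124.000000 387.000000 34.000000 68.000000
1.000000 24.000000 35.000000 1.000000 104.000000 33.000000 1.000000 1.000000 34.000000
45.000000 18.000000 15.000000 5.000000 110.000000 54.000000 21.000000 3.000000 51.000000 385.000000
38.000000 593.000000 123.000000 20.000000 16.000000 309.000000 141.000000 30.000000 76.000000 34.000000 23.000000
235.000000 57.000000 1.000000 1.000000 156.000000 158.000000 1.000000 37.000000 116.000000 375.000000 581.000000 134.000000
1.000000 7.000000 49.000000 1.000000 70.000000 1.000000 1.000000 7.000000 141.000000 64.000000 179.000000 14.000000 247.000000
97.000000 24.000000 33.000000 55.000000 1.000000 68.000000 52.000000 17.000000 44.000000 10.000000 22.000000 43.000000 1.000000 11.000000
460.000000 102.000000 294.000000 136.000000 75.000000 225.000000 95.000000 152.000000 183.000000 4.000000 24.000000 77.000000 1.000000 20.000000 134.000000
258.000000 64.000000 148.000000 55.000000 117.000000 146.000000 82.000000 7.000000 49.000000 72.000000 25.000000 110.000000 131.000000 69.000000 62.000000 671.000000
5.000000 13.000000 16.000000 1.000000 55.000000 10.000000 17.000000 23.000000 48.000000 39.000000 47.000000 6.000000 111.000000 182.000000 9.000000 14.000000 1.000000
55.000000 47.000000 28.000000 1.000000 131.000000 45.000000 1.000000 21.000000 307.000000 26.000000 64.000000 1.000000 74.000000 1017.000000 14.000000 31.000000 34.000000 176.000000
197.000000 29.000000 21.000000 6.000000 295.000000 36.000000 35.000000 3.000000 1.000000 1048.000000 112.000000 19.000000 236.000000 92.000000 25.000000 39.000000 196.000000 26.000000 59.000000

0.064600 0.045300 0.037600 0.042200 0.011400 0.060600 0.060700 0.063900 0.027300 0.067900 0.101800 0.075100 0.015000 0.028700 0.068100 0.048800 0.062200 0.025100 0.031800 0.061900
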