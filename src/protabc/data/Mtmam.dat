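32.000000
2.000000 4.000000
11.000000 0.000000 864.000000
0.000000 186.000000 0.000000 0.000000
0.000000 246.000000 8.000000 49.000000 0.000000
0.000000 0.000000 0.000000 569.000000 0.000000 274.000000
78.000000 18.000000 47.000000 79.000000 0.000000 0.000000 22.000000
8.000000 232.000000 458.000000 11.000000 305.000000 550.000000 22.000000 0.000000
75.000000 0.000000 19.000000 0.000000 41.000000 0.000000 0.000000 0.000000 0.000000
21.000000 6.000000 0.000000 0.000000 27.000000 20.000000 0.000000 0.000000 26.000000 232.000000
0.000000 50.000000 408.000000 0.000000 0.000000 242.000000 215.000000 0.000000 0.000000 6.000000 4.000000
76.000000 0.000000 21.000000 0.000000 0.000000 22.000000 0.000000 0.000000 0.000000 378.000000 609.000000 59.000000
0.000000 0.000000 6.000000 5.000000 7.000000 0.000000 0.000000 0.000000 0.000000 57.000000 246.000000 0.000000 11.000000
53.000000 9.000000 33.000000 2.000000 0.000000 51.000000 0.000000 0.000000 53.000000 5.000000 43.000000 18.000000 0.000000 17.000000
342.000000 3.000000 446.000000 16.000000 347.000000 30.000000 21.000000 112.000000 20.000000 0.000000 74.000000 65.000000 47.000000 90.000000 202.000000
681.000000 0.000000 110.000000 0.000000 114.000000 0.000000 4.000000 0.000000 1.000000 360.000000 34.000000 50.000000 691.000000 8.000000 78.000000 614.000000
5.000000 16.000000 6.000000 0.000000 65.000000 0.000000 0.000000 0.000000 0.000000 0.000000 12.000000 0.000000 13.000000 0.000000 7.000000 17.000000 0.000000
0.000000 0.000000 156.000000 0.000000 530.000000 54.000000 0.000000 1.000000 1525.000000 16.000000 25.000000 67.000000 0.000000 682.000000 8.000000 107.000000 0.000000 14.000000
398.000000 0.000000 0.000000 10.000000 0.000000 33.000000 20.000000 5.000000 0.000000 2220.000000 100.000000 0.000000 832.000000 6.000000 0.000000 0.000000 237.000000 0.000000 0.000000

0.069200 0.018400 0.040000 0.018600 0.006500 0.023800 0.023600 0.055700 0.027700 0.090500 0.167500 0.022100 0.056100 0.061100 0.053600 0.072500 0.087000 0.029300 0.034000 0.042800
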