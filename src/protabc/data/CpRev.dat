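105.000000
227.000000 357.000000
175.000000 43.000000 4435.000000
669.000000 823.000000 538.000000 10.000000
157.000000 1745.000000 768.000000 400.000000 10.000000
499.000000 152.000000 1055.000000 3691.000000 10.000000 3122.000000
665.000000 243.000000 653.000000 431.000000 303.000000 133.000000 379.000000
66.000000 715.000000 1405.000000 331.000000 441.000000 1269.000000 162.000000 19.000000
145.000000 136.000000 168.000000 10.000000 280.000000 92.000000 148.000000 40.000000 29.000000
197.000000 203.000000 113.000000 10.000000 396.000000 286.000000 82.000000 20.000000 66.000000 1745.000000
236.000000 4482.000000 2430.000000 412.000000 48.000000 3313.000000 2629.000000 263.000000 305.000000 345.000000 218.000000
185.000000 125.000000 61.000000 47.000000 159.000000 202.000000 113.000000 21.000000 10.000000 1772.000000 1351.000000 193.000000
68.000000 53.000000 97.000000 22.000000 726.000000 10.000000 145.000000 25.000000 127.000000 454.000000 1268.000000 72.000000 327.000000
490.000000 87.000000 173.000000 170.000000 285.000000 323.000000 185.000000 28.000000 152.000000 117.000000 219.000000 302.000000 100.000000 43.000000
2440.000000 385.000000 2085.000000 590.000000 2331.000000 396.000000 568.000000 691.000000 303.000000 216.000000 516.000000 868.000000 93.000000 487.000000 1202.000000
1340.000000 314.000000 1393.000000 266.000000 576.000000 241.000000 369.000000 92.000000 32.000000 1040.000000 156.000000 918.000000 645.000000 148.000000 260.000000 2151.000000
14.000000 230.000000 40.000000 18.000000 435.000000 53.000000 63.000000 82.000000 69.000000 42.000000 159.000000 10.000000 86.000000 468.000000 49.000000 73.000000 29.000000
56.000000 323.000000 754.000000 281.000000 1466.000000 391.000000 142.000000 10.000000 1971.000000 89.000000 189.000000 247.000000 215.000000 2370.000000 97.000000 522.000000 71.000000 346.000000
968.000000 92.000000 83.000000 75.000000 592.000000 54.000000 200.000000 91.000000 25.000000 4797.000000 865.000000 249.000000 475.000000 317.000000 122.000000 167.000000 760.000000 10.000000 119.000000

0.075500 0.062100 0.041000 0.037100 0.009100 0.038200 0.049500 0.083800 0.024600 0.080600 0.101100 0.050400 0.022000 0.050600 0.043100 0.062200 0.054300 0.018100 0.030700 0.066000
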