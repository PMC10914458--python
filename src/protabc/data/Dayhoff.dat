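27.000000
98.000000 32.000000
120.000000 0.000000 905.000000
36.000000 23.000000 0.000000 0.000000
89.000000 246.000000 103.000000 134.000000 0.000000
198.000000 1.000000 148.000000 1153.000000 0.000000 716.000000
240.000000 9.000000 139.000000 125.000000 11.000000 28.000000 81.000000
23.000000 240.000000 535.000000 86.000000 28.000000 606.000000 43.000000 10.000000
65.000000 64.000000 77.000000 24.000000 44.000000 18.000000 61.000000 0.000000 7.000000
41.000000 15.000000 34.000000 0.000000 0.000000 73.000000 11.000000 7.000000 44.000000 257.000000
26.000000 464.000000 318.000000 71.000000 0.000000 153.000000 83.000000 27.000000 26.000000 46.000000 18.000000
72.000000 90.000000 1.000000 0.000000 0.000000 114.000000 30.000000 17.000000 0.000000 336.000000 527.000000 243.000000
18.000000 14.000000 14.000000 0.000000 0.000000 0.000000 0.000000 15.000000 48.000000 196.000000 157.000000 0.000000 92.000000
250.000000 103.000000 42.000000 13.000000 19.000000 153.000000 51.000000 34.000000 94.000000 12.000000 32.000000 33.000000 17.000000 11.000000
409.000000 154.000000 495.000000 95.000000 161.000000 56.000000 79.000000 234.000000 35.000000 24.000000 17.000000 96.000000 62.000000 46.000000 245.000000
371.000000 26.000000 229.000000 66.000000 16.000000 53.000000 34.000000 30.000000 22.000000 192.000000 33.000000 136.000000 104.000000 13.000000 78.000000 550.000000
0.000000 201.000000 23.000000 0.000000 0.000000 0.000000 0.000000 0.000000 27.000000 0.000000 46.000000 0.000000 0.000000 76.000000 0.000000 75.000000 0.000000
24.000000 8.000000 95.000000 0.000000 96.000000 0.000000 22.000000 0.000000 127.000000 37.000000 28.000000 13.000000 0.000000 698.000000 0.000000 34.000000 42.000000 61.000000
208.000000 24.000000 15.000000 18.000000 49.000000 35.000000 37.000000 54.000000 44.000000 889.000000 175.000000 10.000000 258.000000 12.000000 48.000000 30.000000 157.000000 0.000000 28.000000

0.087127 0.040904 0.040432 0.046872 0.033474 0.038255 0.049530 0.088612 0.033618 0.036886 0.085357 0.080482 0.014753 0.039772 0.050680 0.069577 0.058542 0.010494 0.029916 0.064718
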