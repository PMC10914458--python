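0.307507
0.005000 0.295543
1.455040 0.005000 17.661200
0.123758 0.351721 0.086064 0.005000
0.055113 3.421500 0.672052 0.005000 0.005000
1.481350 0.074922 0.079263 10.587200 0.005000 2.560200
2.135360 3.653450 0.323401 2.838060 0.897871 0.061914 3.927750
0.084761 9.040440 7.645850 1.916900 0.240073 7.055450 0.119740 0.005000
0.005000 0.677289 0.680565 0.017679 0.005000 0.005000 0.006091 0.005000 0.103111
0.215256 0.701427 0.005000 0.008760 0.129777 1.494560 0.005000 0.005000 1.741710 5.958790
0.005000 20.450000 7.904430 0.005000 0.005000 6.547370 4.614820 0.521705 0.005000 0.322319 0.081500
0.018664 2.513940 0.005000 0.005000 0.005000 0.303676 0.175789 0.005000 0.005000 11.206500 5.319610 1.282460
0.014127 0.005000 0.005000 0.005000 9.298150 0.005000 0.005000 0.291561 0.145558 3.398360 8.524840 0.034266 0.188025
2.122170 1.283550 0.007396 0.034266 0.005000 4.472110 0.012023 0.005000 2.453180 0.041059 2.077570 0.031386 0.005000 0.005000
2.466330 3.479100 13.144700 0.528230 4.693140 0.116311 0.005000 4.380410 0.382747 1.218030 0.927656 0.504111 0.005000 0.956472 5.377620
15.918300 2.868680 6.886670 0.274724 0.739969 0.243589 0.289774 0.369615 0.711594 8.612170 0.043767 4.671420 4.940260 0.014127 2.014170 8.931070
0.005000 0.991338 0.005000 0.005000 2.632770 0.026656 0.005000 1.216740 0.069518 0.005000 0.748843 0.005000 0.089078 0.829343 0.044451 0.024873 0.005000
0.005000 0.009918 1.764170 0.674653 7.579320 0.113033 0.079263 0.005000 18.694300 0.148168 0.111986 0.005000 0.005000 15.340000 0.030438 0.648024 0.105652 1.280220
7.614280 0.081245 0.026656 1.047930 0.420027 0.020915 1.028470 0.953155 0.005000 17.738900 1.410360 0.265829 6.853200 0.723274 0.005000 0.074922 0.709226 0.005000 0.041059

0.060490 0.066040 0.044128 0.042109 0.020076 0.053606 0.071567 0.072308 0.022294 0.069731 0.098851 0.056968 0.019768 0.028809 0.046025 0.050604 0.053637 0.033012 0.028350 0.061625
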