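0.074481
0.617509 0.160240
4.435210 0.067454 29.408700
0.167653 2.863640 0.060493 0.005000
0.005000 10.674600 0.342068 0.005000 0.005000
5.563250 0.025163 0.201526 12.123300 0.005000 3.206560
1.868500 13.437900 0.060493 10.396900 0.048980 0.060493 14.780100
0.005000 6.844050 8.598760 2.317790 0.005000 18.546500 0.005000 0.005000
0.005000 1.340690 0.987028 0.145124 0.005000 0.034225 0.039051 0.005000 0.005000
0.160240 0.586757 0.005000 0.005000 0.005000 2.890480 0.129839 0.048980 1.763820 9.102460
0.592784 39.889700 10.665500 0.894313 0.005000 13.070500 23.962600 0.279425 0.224060 0.817481 0.005000
0.005000 3.286520 0.201526 0.005000 0.005000 0.005000 0.005000 0.048980 0.005000 17.306400 11.383900 4.095640
0.597923 0.005000 0.005000 0.005000 0.362959 0.005000 0.005000 0.005000 0.005000 1.482880 7.487810 0.005000 0.005000
1.009810 0.404723 0.344848 0.005000 0.005000 3.045020 0.005000 0.005000 13.944400 0.005000 9.830950 0.111928 0.005000 0.034225
8.594200 8.350240 14.569900 0.427881 1.121950 0.160240 0.005000 6.279660 0.725157 0.740091 6.143960 0.005000 0.392575 4.279390 14.249000
24.142200 0.928203 4.542060 0.630395 0.005000 0.203091 0.458743 0.048980 0.959560 9.363450 0.005000 4.048020 7.413130 0.114512 4.337010 6.340790
0.005000 5.965640 0.005000 0.005000 5.498940 0.044330 0.005000 2.825800 0.005000 0.005000 1.370310 0.005000 0.005000 0.005000 0.005000 1.101560 0.005000
0.005000 0.005000 5.064750 2.281540 8.348350 0.005000 0.005000 0.005000 47.488900 0.114512 0.005000 0.005000 0.579198 4.127280 0.005000 0.933142 0.490608 0.005000
24.809400 0.279425 0.074481 2.917860 0.005000 0.005000 2.199520 2.796220 0.827479 24.823100 2.953440 0.128065 14.768300 2.280000 0.005000 0.862637 0.005000 0.005000 1.354820

0.037749 0.057321 0.089113 0.034203 0.024010 0.043782 0.061861 0.083850 0.015608 0.098364 0.057787 0.064168 0.015842 0.042274 0.045860 0.055085 0.081377 0.019597 0.020585 0.051564
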