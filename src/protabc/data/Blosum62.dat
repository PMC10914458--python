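0.735790
0.485391 1.297447
0.543162 0.500964 3.180100
1.459995 0.227827 0.397359 0.240837
1.199706 3.020834 1.839216 1.190946 0.329802
1.170949 1.360574 1.240489 3.761625 0.140749 5.528919
1.955884 0.418763 1.355872 0.798473 0.418203 0.609846 0.423580
0.716241 1.456141 2.414501 0.778143 0.354058 2.435341 1.626891 0.539859
0.605899 0.232036 0.283017 0.418556 0.774894 0.236202 0.186848 0.189296 0.252718
0.800017 0.622712 0.211888 0.218132 0.831843 0.580737 0.372625 0.217721 0.348072 3.890964
1.295201 5.411115 1.593137 1.032448 0.285079 3.945278 2.802427 0.752042 1.022507 0.406194 0.445570
1.253758 0.983693 0.648441 0.222622 0.767689 2.494896 0.555415 0.459436 0.984312 3.364798 6.030559 1.073061
0.492965 0.371645 0.354861 0.281731 0.441337 0.144357 0.291409 0.368166 0.714534 1.517359 2.064840 0.266925 1.773855
1.173276 0.448134 0.494887 0.730628 0.356008 0.858571 0.926564 0.504087 0.527007 0.388355 0.374556 1.047383 0.454124 0.233598
4.325093 1.122783 2.904102 1.582754 1.197188 1.934871 1.769893 1.509326 1.117030 0.357544 0.352969 1.752166 0.918723 0.540028 1.169130
1.729178 0.914666 1.898174 0.934188 1.119831 1.277480 1.071097 0.641436 0.585407 1.179091 0.915260 1.303875 1.488548 0.488206 1.005452 5.151556
0.465839 0.426382 0.191482 0.145345 0.527664 0.758654 0.407636 0.508359 0.301249 0.341986 0.691475 0.332243 0.888101 2.074325 0.252215 0.387926 0.513128
0.718207 0.720517 0.538223 0.261422 0.470238 0.958990 0.596719 0.308056 4.218954 0.674617 0.811246 0.717993 0.951682 6.747260 0.369405 0.796752 0.801010 4.054419
2.187775 0.438388 0.312859 0.258129 1.116352 0.530786 0.524254 0.253341 0.201556 8.311839 2.231406 0.498138 2.575851 0.838120 0.496908 0.561925 2.253074 0.266509 1.000000

0.074000 0.052000 0.045000 0.054000 0.025000 0.034000 0.054000 0.074000 0.026000 0.068000 0.099000 0.058000 0.025000 0.047000 0.039000 0.057000 0.051000 0.013000 0.032000 0.073000
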