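# Pairwise contact potential derived from Kyte-Doolittle hydropathy:
# U[a,b] = -2 * h'(a) * h'(b), h' = (h + 4.5) / 9.
# Rows/columns in alphabetical one-letter order: A C D E F G H I K L M N P Q R S T V W Y
-0.9800000000 -1.0888888889 -0.1555555556 -0.1555555556 -1.1355555556 -0.6377777778 -0.2022222222 -1.4000000000 -0.0933333333 -1.2911111111 -0.9955555556 -0.1555555556 -0.4511111111 -0.1555555556 -0.0000000000 -0.5755555556 -0.5911111111 -1.3533333333 -0.5600000000 -0.4977777778
-1.0888888889 -1.2098765432 -0.1728395062 -0.1728395062 -1.2617283951 -0.7086419753 -0.2246913580 -1.5555555556 -0.1037037037 -1.4345679012 -1.1061728395 -0.1728395062 -0.5012345679 -0.1728395062 -0.0000000000 -0.6395061728 -0.6567901235 -1.5037037037 -0.6222222222 -0.5530864198
-0.1555555556 -0.1728395062 -0.0246913580 -0.0246913580 -0.1802469136 -0.1012345679 -0.0320987654 -0.2222222222 -0.0148148148 -0.2049382716 -0.1580246914 -0.0246913580 -0.0716049383 -0.0246913580 -0.0000000000 -0.0913580247 -0.0938271605 -0.2148148148 -0.0888888889 -0.0790123457
-0.1555555556 -0.1728395062 -0.0246913580 -0.0246913580 -0.1802469136 -0.1012345679 -0.0320987654 -0.2222222222 -0.0148148148 -0.2049382716 -0.1580246914 -0.0246913580 -0.0716049383 -0.0246913580 -0.0000000000 -0.0913580247 -0.0938271605 -0.2148148148 -0.0888888889 -0.0790123457
-1.1355555556 -1.2617283951 -0.1802469136 -0.1802469136 -1.3158024691 -0.7390123457 -0.2343209877 -1.6222222222 -0.1081481481 -1.4960493827 -1.1535802469 -0.1802469136 -0.5227160494 -0.1802469136 -0.0000000000 -0.6669135802 -0.6849382716 -1.5681481481 -0.6488888889 -0.5767901235
-0.6377777778 -0.7086419753 -0.1012345679 -0.1012345679 -0.7390123457 -0.4150617284 -0.1316049383 -0.9111111111 -0.0607407407 -0.8402469136 -0.6479012346 -0.1012345679 -0.2935802469 -0.1012345679 -0.0000000000 -0.3745679012 -0.3846913580 -0.8807407407 -0.3644444444 -0.3239506173
-0.2022222222 -0.2246913580 -0.0320987654 -0.0320987654 -0.2343209877 -0.1316049383 -0.0417283951 -0.2888888889 -0.0192592593 -0.2664197531 -0.2054320988 -0.0320987654 -0.0930864198 -0.0320987654 -0.0000000000 -0.1187654321 -0.1219753086 -0.2792592593 -0.1155555556 -0.1027160494
-1.4000000000 -1.5555555556 -0.2222222222 -0.2222222222 -1.6222222222 -0.9111111111 -0.2888888889 -2.0000000000 -0.1333333333 -1.8444444444 -1.4222222222 -0.2222222222 -0.6444444444 -0.2222222222 -0.0000000000 -0.8222222222 -0.8444444444 -1.9333333333 -0.8000000000 -0.7111111111
-0.0933333333 -0.1037037037 -0.0148148148 -0.0148148148 -0.1081481481 -0.0607407407 -0.0192592593 -0.1333333333 -0.0088888889 -0.1229629630 -0.0948148148 -0.0148148148 -0.0429629630 -0.0148148148 -0.0000000000 -0.0548148148 -0.0562962963 -0.1288888889 -0.0533333333 -0.0474074074
-1.2911111111 -1.4345679012 -0.2049382716 -0.2049382716 -1.4960493827 -0.8402469136 -0.2664197531 -1.8444444444 -0.1229629630 -1.7009876543 -1.3116049383 -0.2049382716 -0.5943209877 -0.2049382716 -0.0000000000 -0.7582716049 -0.7787654321 -1.7829629630 -0.7377777778 -0.6558024691
-0.9955555556 -1.1061728395 -0.1580246914 -0.1580246914 -1.1535802469 -0.6479012346 -0.2054320988 -1.4222222222 -0.0948148148 -1.3116049383 -1.0113580247 -0.1580246914 -0.4582716049 -0.1580246914 -0.0000000000 -0.5846913580 -0.6004938272 -1.3748148148 -0.5688888889 -0.5056790123
-0.1555555556 -0.1728395062 -0.0246913580 -0.0246913580 -0.1802469136 -0.1012345679 -0.0320987654 -0.2222222222 -0.0148148148 -0.2049382716 -0.1580246914 -0.0246913580 -0.0716049383 -0.0246913580 -0.0000000000 -0.0913580247 -0.0938271605 -0.2148148148 -0.0888888889 -0.0790123457
-0.4511111111 -0.5012345679 -0.0716049383 -0.0716049383 -0.5227160494 -0.2935802469 -0.0930864198 -0.6444444444 -0.0429629630 -0.5943209877 -0.4582716049 -0.0716049383 -0.2076543210 -0.0716049383 -0.0000000000 -0.2649382716 -0.2720987654 -0.6229629630 -0.2577777778 -0.2291358025
-0.1555555556 -0.1728395062 -0.0246913580 -0.0246913580 -0.1802469136 -0.1012345679 -0.0320987654 -0.2222222222 -0.0148148148 -0.2049382716 -0.1580246914 -0.0246913580 -0.0716049383 -0.0246913580 -0.0000000000 -0.0913580247 -0.0938271605 -0.2148148148 -0.0888888889 -0.0790123457
-0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000 -0.0000000000
-0.5755555556 -0.6395061728 -0.0913580247 -0.0913580247 -0.6669135802 -0.3745679012 -0.1187654321 -0.8222222222 -0.0548148148 -0.7582716049 -0.5846913580 -0.0913580247 -0.2649382716 -0.0913580247 -0.0000000000 -0.3380246914 -0.3471604938 -0.7948148148 -0.3288888889 -0.2923456790
-0.5911111111 -0.6567901235 -0.0938271605 -0.0938271605 -0.6849382716 -0.3846913580 -0.1219753086 -0.8444444444 -0.0562962963 -0.7787654321 -0.6004938272 -0.0938271605 -0.2720987654 -0.0938271605 -0.0000000000 -0.3471604938 -0.3565432099 -0.8162962963 -0.3377777778 -0.3002469136
-1.3533333333 -1.5037037037 -0.2148148148 -0.2148148148 -1.5681481481 -0.8807407407 -0.2792592593 -1.9333333333 -0.1288888889 -1.7829629630 -1.3748148148 -0.2148148148 -0.6229629630 -0.2148148148 -0.0000000000 -0.7948148148 -0.8162962963 -1.8688888889 -0.7733333333 -0.6874074074
-0.5600000000 -0.6222222222 -0.0888888889 -0.0888888889 -0.6488888889 -0.3644444444 -0.1155555556 -0.8000000000 -0.0533333333 -0.7377777778 -0.5688888889 -0.0888888889 -0.2577777778 -0.0888888889 -0.0000000000 -0.3288888889 -0.3377777778 -0.7733333333 -0.3200000000 -0.2844444444
-0.4977777778 -0.5530864198 -0.0790123457 -0.0790123457 -0.5767901235 -0.3239506173 -0.1027160494 -0.7111111111 -0.0474074074 -0.6558024691 -0.5056790123 -0.0790123457 -0.2291358025 -0.0790123457 -0.0000000000 -0.2923456790 -0.3002469136 -0.6874074074 -0.2844444444 -0.2528395062
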