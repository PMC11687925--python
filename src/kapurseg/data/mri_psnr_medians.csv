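image_id,n_thresholds,SSA,PSO,GA,QPSO,PSOH,CIWP-PSO
Image a,4,24.5956,24.4424,24.0684,24.8832,24.438,24.8856
Image a,6,26.3348,28.049,27.8483,26.2756,26.2291,28.4368
Image a,8,28.7647,29.3914,26.5176,29.9011,30.0931,29.3003
Image b,4,23.3883,25.2679,24.113,25.2565,25.2679,25.2679
Image b,6,26.2105,27.063,25.2804,27.4936,26.7867,27.5584
Image b,8,28.1319,30.3192,26.7587,29.8971,29.9732,30.5169
Image c,4,23.6106,24.2259,24.5974,24.6018,24.2281,24.2281
Image c,6,26.6892,27.9431,24.437,28.0154,28.0165,27.886
Image c,8,27.5465,28.8074,26.0483,28.8971,30.2043,30.254
Image d,4,21.5142,29.0857,29.4623,29.5618,29.0933,29.1042
Image d,6,30.4084,32.0062,31.6368,32.0213,32.0611,32.0717
Image d,8,28.9961,32.6642,30.9393,32.4456,32.517,34.3149
Image e,4,24.5849,24.4971,21.887,24.0198,24.5157,24.3406
Image e,6,24.8053,25.6286,26.7176,27.8756,25.6796,27.7922
Image e,8,23.7975,28.8294,26.3156,28.2873,26.2406,28.7917
Image f,4,20.7115,24.0274,21.9493,23.9028,18.0608,24.1172
Image f,6,26.3088,26.2045,25.905,26.2368,26.3075,26.246
Image f,8,23.2794,28.7626,26.5044,25.9082,28.1359,29.2011
Image g,4,20.9483,23.0312,21.1176,24.2066,22.9989,23.0009
Image g,6,20.5896,26.9839,24.9636,26.7805,26.8121,26.9817
Image g,8,24.7884,28.2808,23.8363,28.2901,28.9912,28.7103
Image h,4,22.4163,22.631,21.5582,20.9833,22.6158,22.7016
Image h,6,22.7711,26.5491,24.9036,25.1744,24.4323,26.4835
Image h,8,27.0744,26.4006,26.8735,27.3181,28.4173,27.4012
Image i,4,21.3263,21.6911,23.9697,21.0206,21.8994,21.4545
Image i,6,22.326,27.2714,24.3483,27.4192,27.3705,27.3524
Image i,8,21.2451,29.4433,28.4556,29.3211,29.6301,29.6972
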