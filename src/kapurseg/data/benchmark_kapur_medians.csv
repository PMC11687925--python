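image_id,n_thresholds,GWO,WOA,SSA,PSO,GA,FA,QPSO,PSOH,CIWP-PSO
Image (1),4,19.253,19.258,19.2602,19.2648,19.2138,19.2646,19.2648,19.2648,19.2648
Image (1),6,24.5055,24.638,23.9808,24.7973,24.5618,24.7859,24.7991,24.7977,24.7649
Image (1),8,29.2532,29.3396,28.8557,29.7289,29.465,29.7229,29.7643,29.684,29.7686
Image (2),4,17.4345,17.437,16.8056,17.4656,17.0658,17.4539,17.4656,17.4244,17.4656
Image (2),6,22.4739,22.3895,21.4848,22.5377,22.0004,22.4711,22.5025,22.4342,22.5483
Image (2),8,26.6023,26.2393,25.0013,27.2971,26.0451,27.0313,27.2056,26.4428,27.2059
Image (3),4,18.5586,18.5454,18.0493,18.5604,18.3462,18.5567,18.5604,18.5604,18.5604
Image (3),6,23.5979,23.6578,23.6803,23.8289,23.1354,23.8025,23.7762,23.7364,23.8324
Image (3),8,28.1419,28.2484,27.3824,28.5587,28.0036,28.568,28.6257,28.3676,28.7423
Image (4),4,19.0601,19.072,18.7946,19.075,18.5146,19.077,19.0771,19.0768,19.0771
Image (4),6,24.318,24.4345,24.4875,24.5336,24.3551,24.5018,24.5336,24.5298,24.5372
Image (4),8,28.8973,29.0716,28.8425,29.3124,28.8445,29.2552,29.3195,29.2929,29.1532
Image (5),4,18.2265,18.3074,18.2789,18.3092,18.272,18.3082,18.3088,18.3059,18.3092
Image (5),6,23.4263,23.5921,23.049,23.6953,22.9654,23.6768,23.6802,23.6898,23.6855
Image (5),8,28.0565,28.3972,27.9515,28.489,27.8459,28.4848,28.5083,28.5148,28.5259
Image (6),4,18.1017,18.2391,18.0804,18.2516,18.1181,18.2377,18.2516,18.2436,18.2516
Image (6),6,23.1478,23.4681,22.496,23.6669,23.0124,23.6024,23.3013,23.6478,23.5369
Image (6),8,27.3323,28.1239,27.6357,27.8718,28.2484,28.4494,28.3565,28.4315,28.5337
Image (7),4,18.7721,18.861,18.7516,18.8655,18.4312,18.854,18.8663,18.8621,18.8663
Image (7),6,24.2425,24.3202,23.88,24.3848,23.7698,24.3747,24.3994,24.3974,24.4029
Image (7),8,28.5599,28.7419,28.6786,29.0484,28.4469,29.255,29.3163,28.9922,29.2052
Image (8),4,18.316,18.6148,18.2677,18.6336,18.27,18.6266,18.6336,18.4949,18.6336
Image (8),6,23.4959,23.697,23.4241,23.972,23.7224,23.9504,23.894,23.8604,23.9861
Image (8),8,28.1317,28.7224,27.6563,28.7183,28.0367,28.7701,28.8661,28.8444,28.859
Image (9),4,18.3066,18.616,18.2439,18.6203,17.9432,18.6193,18.6204,18.6176,18.6204
Image (9),6,23.661,24.2313,23.1777,24.2612,24.0979,24.2252,24.2891,24.0959,24.2897
Image (9),8,27.8629,28.251,28.2173,28.8428,27.9384,28.9796,29.0295,28.9706,29.0847
Image (10),4,18.6903,18.7245,18.5134,18.7418,18.2935,18.741,18.7419,18.7405,18.7419
Image (10),6,23.8911,24.0499,23.7531,24.1714,23.6303,24.0988,24.1716,24.1238,24.171
Image (10),8,28.0086,28.8064,26.9977,28.9975,28.2025,28.9292,29.0382,28.7585,29.0394
Image (11),4,18.6715,18.761,18.2863,18.8055,18.6567,18.804,18.7702,18.8034,18.8055
Image (11),6,23.9887,24.2161,23.8558,24.3287,23.9896,24.3287,24.3504,24.3512,24.3526
Image (11),8,28.6289,29.0719,28.7293,29.2135,29.0616,29.2712,29.2866,29.262,29.3022
Image (12),4,18.5393,18.7374,18.691,18.7438,18.6014,18.7442,18.7454,18.7374,18.7454
Image (12),6,23.6718,23.7419,23.6794,23.8403,23.4517,23.8322,23.8102,23.8571,23.8645
Image (12),8,27.7621,28.4357,28.4815,28.657,27.8965,28.4772,28.2981,28.329,28.7221
Image (13),4,18.4063,18.4738,18.2103,18.4804,18.4232,18.4787,18.4801,18.4797,18.4805
Image (13),6,23.6792,23.7915,23.47,23.7745,23.2706,23.8148,23.8309,23.7681,23.8654
Image (13),8,28.1499,28.0849,27.2499,28.8345,28.0154,28.7238,28.7792,28.8126,28.8678
Image (14),4,18.4525,18.8619,18.3746,18.8628,18.6329,18.8532,18.8382,18.8023,18.8629
Image (14),6,23.1689,24.1581,23.7308,24.4324,23.873,24.4027,24.4267,24.331,24.458
Image (14),8,28.8381,29.2196,28.402,29.2558,28.051,29.3137,29.4066,29.2511,29.405
Image (15),4,18.2989,18.3223,18.2607,18.3239,18.0803,18.3155,18.3239,18.2622,18.3239
Image (15),6,23.3824,23.7814,22.6488,23.8537,23.208,23.788,23.8686,23.879,23.8807
Image (15),8,27.9095,28.1218,27.9965,28.6711,28.0682,28.6045,28.7148,28.4722,28.7161
Image (16),4,18.6888,18.683,18.5055,18.6889,18.4954,18.6847,18.6889,18.6863,18.6889
Image (16),6,23.9869,24.1024,24.1087,24.2183,23.9767,24.1943,24.23,24.1703,24.2301
Image (16),8,28.4036,28.8749,28.8226,29.051,28.7741,29.1067,29.0721,28.8101,29.2301
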