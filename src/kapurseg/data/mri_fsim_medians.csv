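image_id,n_thresholds,SSA,PSO,GA,QPSO,PSOH,CIWP-PSO
Image a,4,0.51118,0.498133,0.479006,0.502131,0.515625,0.519682
Image a,6,0.550385,0.574165,0.569204,0.571233,0.559974,0.587774
Image a,8,0.605582,0.624349,0.563663,0.615234,0.61459,0.604338
Image b,4,0.404999,0.445692,0.424475,0.445692,0.430914,0.445692
Image b,6,0.496854,0.509182,0.468541,0.512343,0.526501,0.503088
Image b,8,0.513179,0.585093,0.517067,0.573214,0.553769,0.583868
Image c,4,0.396279,0.398926,0.417281,0.409412,0.400722,0.407108
Image c,6,0.488097,0.489188,0.425551,0.458765,0.489894,0.490643
Image c,8,0.490016,0.528547,0.497866,0.534532,0.517416,0.543275
Image d,4,0.371156,0.414142,0.414967,0.434254,0.440542,0.413704
Image d,6,0.464828,0.492112,0.50281,0.484352,0.491967,0.488047
Image d,8,0.470352,0.521157,0.473794,0.534525,0.519268,0.548054
Image e,4,0.503415,0.473258,0.482224,0.523414,0.516818,0.505943
Image e,6,0.524406,0.527902,0.552767,0.554235,0.582004,0.569329
Image e,8,0.533025,0.582276,0.568359,0.582534,0.590937,0.597466
Image f,4,0.41903,0.497257,0.421261,0.434524,0.482861,0.492476
Image f,6,0.539953,0.530858,0.558701,0.543523,0.548046,0.525067
Image f,8,0.479105,0.613659,0.561443,0.592345,0.405194,0.619356
Image g,4,0.418193,0.461028,0.442636,0.464525,0.489799,0.448729
Image g,6,0.457745,0.559622,0.514171,0.545635,0.546131,0.56006
Image g,8,0.537376,0.587383,0.520971,0.608456,0.595611,0.604149
Image h,4,0.48775,0.490482,0.484315,0.484535,0.406806,0.496913
Image h,6,0.516663,0.57744,0.551677,0.554366,0.556101,0.564578
Image h,8,0.589432,0.573465,0.608449,0.645636,0.586851,0.608605
Image i,4,0.432857,0.448682,0.443268,0.447867,0.334914,0.43102
Image i,6,0.452565,0.548361,0.509525,0.519435,0.544373,0.527984
Image i,8,0.435531,0.614393,0.590084,0.619455,0.600577,0.625999
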