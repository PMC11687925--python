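image_id,n_thresholds,SSA,PSO,GA,QPSO,PSOH,CIWP-PSO
Image a,4,0.694596,0.66725,0.691994,0.693592,0.667901,0.711307
Image a,6,0.720311,0.751242,0.744642,0.735561,0.727089,0.75532
Image a,8,0.761517,0.762948,0.763223,0.770233,0.775225,0.763491
Image b,4,0.622866,0.650561,0.639527,0.640713,0.650561,0.652481
Image b,6,0.64724,0.663727,0.651395,0.679216,0.678423,0.664423
Image b,8,0.677471,0.696654,0.646472,0.687862,0.693686,0.701726
Image c,4,0.638435,0.64439,0.628664,0.643562,0.646514,0.644272
Image c,6,0.657739,0.683289,0.657381,0.685791,0.689769,0.686394
Image c,8,0.692291,0.689734,0.646014,0.699232,0.69076,0.703986
Image d,4,0.539514,0.692611,0.693853,0.691846,0.688003,0.693162
Image d,6,0.687932,0.716193,0.710888,0.715883,0.713196,0.715679
Image d,8,0.689878,0.722963,0.70441,0.723154,0.706841,0.725679
Image e,4,0.70076,0.710189,0.664628,0.710931,0.710225,0.710762
Image e,6,0.716324,0.72145,0.716107,0.737548,0.741241,0.743791
Image e,8,0.70452,0.750253,0.748395,0.733484,0.74197,0.75241
Image f,4,0.489979,0.542575,0.457057,0.480349,0.537305,0.546936
Image f,6,0.620898,0.644896,0.57903,0.643473,0.641281,0.64478
Image f,8,0.590216,0.671775,0.609616,0.672342,0.528978,0.69312
Image g,4,0.601838,0.639844,0.613375,0.642374,0.657518,0.639888
Image g,6,0.587923,0.694489,0.654115,0.692234,0.693441,0.694551
Image g,8,0.650846,0.713883,0.669745,0.718324,0.716355,0.718261
Image h,4,0.564432,0.574259,0.576743,0.568923,0.369055,0.579174
Image h,6,0.575382,0.674987,0.613475,0.647632,0.634147,0.677113
Image h,8,0.677199,0.688304,0.658582,0.689234,0.682787,0.68193
Image i,4,0.539143,0.550148,0.636964,0.592342,0.33265,0.542314
Image i,6,0.649444,0.714793,0.641287,0.713432,0.716685,0.715605
Image i,8,0.621893,0.740898,0.70444,0.743243,0.742585,0.744294
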