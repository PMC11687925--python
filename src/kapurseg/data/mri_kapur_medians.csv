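image_id,n_thresholds,GWO,WOA,SSA,PSO,GA,FA,QPSO,PSOH,CIWP-PSO
Image a,4,28.8526,28.9529,28.892,28.9278,28.7314,28.9541,28.8372,28.955,28.9558
Image a,6,38.5452,39.4726,38.731,39.5246,39.3496,39.6419,39.6761,39.6509,39.5794
Image a,8,48.9602,48.9863,48.575,49.6855,48.2923,49.6574,49.6023,49.5954,49.7089
Image b,4,28.2933,28.7414,27.8398,28.7852,28.5478,28.7745,28.7413,28.7813,28.7852
Image b,6,38.2879,39.0177,37.4522,39.1449,38.0368,39.188,39.1564,39.1563,39.1343
Image b,8,47.4757,48.9497,48.2478,48.8609,47.5649,48.8452,49.1102,48.9905,49.1231
Image c,4,28.7669,29.1591,28.9383,29.1776,28.7367,29.1695,29.1778,29.1705,29.1778
Image c,6,39.1816,39.786,39.2533,39.9822,39.0169,39.9434,39.9458,39.9933,39.9917
Image c,8,49.4891,49.5101,48.6948,49.9807,48.3729,49.9433,50.0601,49.9587,50.0902
Image d,4,26.7475,27.3979,25.7192,27.4075,26.8845,27.3766,27.4081,27.3989,27.4067
Image d,6,36.0916,37.0784,36.5904,37.2134,36.1556,37.0716,37.2098,37.1877,37.2159
Image d,8,45.1746,46.1122,40.7018,46.1324,44.9182,45.8545,46.3018,45.9858,46.4223
Image e,4,29.2168,29.2937,29.244,29.2959,29.0435,29.293,29.2957,29.2948,29.2967
Image e,6,39.2094,39.9737,38.4882,40.0398,39.5375,40.0207,40.0612,40.0058,40.0045
Image e,8,48.4343,50.0213,45.9791,50.1839,49.7253,50.1525,49.8672,50.1893,50.1997
Image f,4,29.2852,29.3818,28.8593,29.3867,28.8757,29.3799,29.3498,29.3853,29.3871
Image f,6,39.1243,39.288,38.3894,39.3356,38.8668,39.293,39.3481,39.339,39.3392
Image f,8,48.0323,43.9579,46.771,48.6675,48.0278,48.747,48.6379,48.8998,49.0636
Image g,4,29.4077,29.4824,28.7575,29.4967,29.2431,29.476,29.4973,29.4895,29.4973
Image g,6,39.5853,39.9839,39.1342,40.1848,39.5956,40.12,40.1816,40.1858,40.1851
Image g,8,48.8233,49.9339,47.2116,49.8371,48.8032,49.9474,50.0849,50.0123,50.1022
Image h,4,29.8018,30.0989,30.0862,30.1068,29.898,30.1035,30.1082,30.007,30.1076
Image h,6,40.1544,40.6746,39.9839,40.7449,39.845,40.698,40.7319,40.691,40.7511
Image h,8,49.4527,50.4936,49.0214,50.8421,49.6848,50.7354,50.8956,50.9198,50.9613
Image i,4,28.5991,28.9556,28.7725,28.957,28.6052,28.9566,28.9631,28.9631,28.9641
Image i,6,38.6742,39.0503,37.8233,39.147,38.134,39.088,39.1514,39.1471,39.1485
Image i,8,47.7414,48.55,44.7868,48.8982,47.529,48.597,48.8952,48.8169,48.9058
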