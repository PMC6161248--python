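hmdb_id,median_umol_l,ci_lower,ci_upper
HMDB0001906,1.128,0.809,1.509
HMDB0000725,15.895,11.300,21.184
HMDB0000472,0.043,0.031,0.058
HMDB0001539,0.963,0.248,2.230
HMDB0000161,477.946,339.667,635.383
HMDB0000510,2.121,1.502,2.818
HMDB0000517,84.902,60.795,113.172
HMDB0000168,47.204,33.635,62.727
HMDB0000191,26.932,18.786,35.424
HMDB0000043,100.045,72.251,134.758
HMDB0000904,27.815,19.812,36.972
HMDB0000064,61.180,44.481,82.161
HMDB0000562,66.085,47.095,88.066
HMDB0000099,0.131,0.093,0.174
HMDB0000092,3.541,2.521,4.733
HMDB0000112,0.195,0.138,0.259
HMDB0001049,2.966,2.116,3.946
HMDB0000148,53.446,37.691,70.613
HMDB0000641,791.142,560.999,1050.605
HMDB0000125,0.021,0.015,0.028
HMDB0000123,243.717,172.929,325.417
HMDB0000128,2.635,1.880,3.498
HMDB0000177,88.616,62.718,117.848
HMDB0000742,0.480,0.124,1.153
HMDB0000719,0.337,0.240,0.448
HMDB0000732,0.096,0.068,0.128
HMDB0000172,83.316,58.352,110.232
HMDB0000684,1.146,0.813,1.520
HMDB0000687,126.072,90.139,167.353
HMDB0000182,176.519,127.474,236.393
HMDB0000696,29.201,21.081,39.249
HMDB0000214,90.177,65.043,120.796
HMDB0000159,88.326,63.916,117.977
HMDB0000162,251.689,180.529,335.079
HMDB0003334,2.862,2.060,3.834
HMDB0000187,148.482,107.012,198.507
HMDB0000167,152.013,108.810,203.651
HMDB0000929,33.961,24.104,45.261
HMDB0000158,65.558,45.778,86.262
HMDB0000883,394.932,282.460,526.776
HMDB0001476,0.188,0.134,0.251
HMDB0000714,6.101,4.362,8.124
HMDB0000033,0.014,0.010,0.019
HMDB0000210,0.310,0.220,0.411
HMDB0000518,53.661,38.588,71.987
HMDB0000619,0.676,0.483,0.900
HMDB0000138,0.373,0.267,0.498
HMDB0000951,0.507,0.359,0.673
HMDB0001548,1.273,0.919,1.710
HMDB0001051,239.946,172.630,322.782
HMDB0000258,1.417,1.015,1.886
HMDB0001257,33.601,23.958,44.759
HMDB0000254,7.912,5.597,10.491
HMDB0000201,9.709,2.323,22.264
HMDB0000651,0.305,0.087,0.720
HMDB0000705,0.055,0.015,0.129
HMDB0000736,0.248,0.061,0.578
HMDB0000688,0.102,0.027,0.240
HMDB0000791,0.297,0.076,0.691
HMDB0000824,0.423,0.119,0.998
HMDB0000121,0.011,0.003,0.027
HMDB0000127,1.960,1.404,2.627
HMDB0000898,0.006,0.004,0.008
HMDB0000462,2.447,1.741,3.254
HMDB0000763,0.074,0.053,0.099
HMDB0000060,6.713,4.798,8.988
HMDB0000224,3.316,2.356,4.420
HMDB0000251,221.359,156.971,294.936
HMDB0000036,0.083,0.060,0.112
HMDB0000925,1.477,1.055,1.973
HMDB0000130,0.115,0.082,0.153
HMDB0000819,0.0010,0.0007,0.0014
HMDB0000845,0.005,0.004,0.007
HMDB0000034,0.007,0.005,0.009
HMDB0000050,0.008,0.006,0.011
HMDB0000045,0.106,0.075,0.140
HMDB0000058,0.005,0.003,0.006
HMDB0001314,0.009,0.002,0.026
HMDB0000133,0.445,0.315,0.593
HMDB0000157,58.838,41.908,78.087
HMDB0000175,0.212,0.151,0.282
HMDB0000195,36.061,25.798,48.008
HMDB0000292,3.926,2.790,5.211
HMDB0000299,0.352,0.249,0.466
HMDB0000017,0.057,0.042,0.077
HMDB0001046,0.531,0.382,0.710
HMDB0000902,0.015,0.011,0.020
HMDB0001406,0.395,0.279,0.524
HMDB0001488,0.012,0.009,0.017
HMDB0000239,0.0007,0.0005,0.0009
HMDB0000089,0.003,0.002,0.004
HMDB0000630,0.080,0.056,0.106
HMDB0000014,0.871,0.440,1.461
HMDB0000012,0.543,0.391,0.726
HMDB0000226,0.036,0.006,0.096
HMDB0000286,0.232,0.165,0.308
HMDB0000300,0.058,0.042,0.078
HMDB0000062,85.669,61.210,114.060
HMDB0000097,95.170,67.565,126.279
HMDB0000715,0.044,0.031,0.058
HMDB0000211,16.989,12.075,22.606
HMDB0000247,3.692,2.617,4.904
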