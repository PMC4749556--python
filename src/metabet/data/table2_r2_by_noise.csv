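experiment,subject,r2_sigma_0.0,r2_sigma_0.1,r2_sigma_0.2,r2_sigma_0.3
1,1,0.465,0.459,0.456,0.447
1,2,0.580,0.578,0.565,0.544
1,3,0.470,0.464,0.448,0.428
1,4,0.396,0.392,0.381,0.363
1,5,0.649,0.655,0.645,0.628
1,6,0.480,0.473,0.458,0.434
1,7,0.453,0.452,0.444,0.427
1,8,0.602,0.595,0.583,0.563
1,9,0.503,0.509,0.512,0.504
2,1,0.624,0.624,0.622,0.612
2,2,0.783,0.780,0.775,0.766
2,3,0.777,0.778,0.767,0.753
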