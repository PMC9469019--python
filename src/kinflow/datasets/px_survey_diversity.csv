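population,time_code,na,ne,shannon,ho,he,ar
FJ1,1,8,3.558,1.437,0.546,0.654,8.43
FL1,1,9.333,4.411,1.527,0.53,0.656,4.084
GD1,1,7.467,3.754,1.443,0.518,0.665,4.503
GX1,1,8.6,3.954,1.522,0.557,0.685,8.008
GZ1,1,8.867,4.47,1.595,0.557,0.708,4.278
HN1,1,8.267,4.127,1.512,0.565,0.686,4.83
JX1,1,8.467,4.033,1.474,0.564,0.644,4.611
MY1,1,9,4.367,1.563,0.596,0.683,8.158
TW1,1,8.4,3.897,1.462,0.575,0.655,18.301
VN1,1,8.067,4.129,1.501,0.579,0.681,13.174
XX1,1,5.2,3.312,1.239,0.549,0.622,5.941
YN1,1,9.133,4.214,1.575,0.572,0.693,9.174
FJ2,2,5.4,3.169,1.173,0.555,0.575,6.987
FL2,2,4.533,2.913,1.084,0.459,0.567,2.747
GD2,2,8.4,4.1,1.461,0.531,0.651,3.139
GX2,2,4.733,2.932,1.042,0.354,0.535,5.616
GZ2,2,5.267,2.62,1.038,0.362,0.508,3.478
HN2,2,4.667,2.795,1.087,0.46,0.564,3.713
JX2,2,8.333,3.466,1.437,0.468,0.637,4.016
MY2,2,6.533,3.078,1.228,0.469,0.59,6.19
TW2,2,7.2,3.797,1.426,0.515,0.655,9.368
VN2,2,6.4,3.477,1.32,0.431,0.62,8.034
XX2,2,3.533,1.685,0.634,0.289,0.342,4.66
FJ3,3,5.533,2.919,1.159,0.517,0.582,3.867
FL3,3,5.867,2.855,1.183,0.471,0.583,2.192
GD3,3,4.867,2.665,1.005,0.424,0.517,2.426
GX3,3,4.667,2.33,0.906,0.361,0.455,2.745
GZ3,3,5.933,3.243,1.28,0.471,0.625,2.358
HN3,3,2.6,2.017,0.701,0.363,0.411,2.324
JX3,3,7.267,3.734,1.434,0.538,0.668,2.808
MY3,3,6.267,2.892,1.173,0.453,0.568,3.275
TW3,3,5.533,2.852,1.181,0.488,0.6,4.291
VN3,3,4.8,2.769,1.093,0.484,0.559,3.771
XX3,3,5.067,2.875,1.124,0.466,0.567,2.772
YN3,3,6,2.879,1.12,0.557,0.532,3.927
YC3,3,3.733,2.131,0.88,0.51,0.476,3.449
FJ4,4,5.933,3.366,1.263,0.453,0.605,4.116
FL4,4,5.333,3.179,1.242,0.446,0.631,2.45
GD4,4,4.933,2.676,1.081,0.374,0.55,2.301
GB4,4,5.733,3.295,1.25,0.446,0.608,3.979
GL4,4,5.867,2.949,1.134,0.447,0.548,2.812
HN4,4,6.067,3.017,1.148,0.438,0.554,3.005
JX4,4,6.333,3.245,1.279,0.461,0.602,3.231
JX5,4,2.6,1.827,0.618,0.3,0.347,4.001
MY4,4,6.8,3.262,1.221,0.504,0.578,5.84
TW4,4,3.8,2.149,0.892,0.351,0.49,5.201
VN4,4,6.333,3.391,1.279,0.575,0.604,3.005
YN4,4,9,3.738,1.478,0.525,0.65,5.134
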