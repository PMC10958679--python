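age,low,medium,high
40,2.445,3.520,4.656
41,2.471,3.551,4.673
42,2.546,3.600,4.709
43,2.559,3.629,4.756
44,2.587,3.653,4.764
45,2.612,3.673,4.779
46,2.667,3.767,4.920
47,2.667,3.776,4.930
48,2.687,3.780,4.928
49,2.761,3.834,4.957
50,2.808,3.860,4.966
51,2.806,3.859,4.979
52,2.852,3.904,5.000
53,2.863,3.914,5.010
54,2.859,3.888,4.955
55,2.863,3.886,4.962
56,2.868,3.901,4.980
57,2.882,3.904,4.981
58,2.886,3.891,4.953
59,2.900,3.929,5.029
60,2.902,3.928,5.036
61,2.900,3.930,5.032
62,2.905,3.942,5.058
63,2.906,3.938,5.056
64,2.903,3.936,5.066
65,2.912,3.953,5.080
66,2.914,3.960,5.084
67,2.910,3.907,5.004
68,2.879,3.906,5.069
69,2.870,3.893,5.068
70,2.868,3.868,5.024
71,2.865,3.842,4.952
72,2.812,3.805,4.902
73,2.808,3.783,4.880
74,2.811,3.817,4.987
75,2.789,3.777,4.886
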