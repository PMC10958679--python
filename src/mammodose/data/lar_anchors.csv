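age,incidence_per_100k_per_0p1Gy,mortality_per_100k_per_0p1Gy
40,141,35
50,70,19
60,31,9
70,12,5
80,4,2
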