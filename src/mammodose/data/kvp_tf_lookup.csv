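cbt_low_mm,cbt_high_mm,kvp,target_filter
20,24,25,W/Rh
25,34,26,W/Rh
35,39,27,W/Rh
40,49,28,W/Rh
50,54,29,W/Rh
55,59,30,W/Rh
60,64,31,W/Rh
65,69,32,W/Rh
70,74,30,W/Ag
75,79,31,W/Ag
80,84,32,W/Ag
85,89,33,W/Ag
90,94,34,W/Ag
95,99,35,W/Ag
100,104,36,W/Ag
105,110,37,W/Ag
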