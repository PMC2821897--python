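age_min,age_max,weight
0,17,0.40
18,34,0.55
35,44,0.75
45,54,1.00
55,64,1.45
65,74,1.90
75,84,2.20
85,119,2.40
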