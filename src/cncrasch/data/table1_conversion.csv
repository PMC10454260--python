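original_total,measure_8item,measure_10item
40,,-4.18
38,,-2.97
36,,-2.25
34,,-1.81
32,-3.81,-1.48
30,-2.59,-1.21
28,-1.86,-0.96
26,-1.40,-0.74
24,-1.04,-0.53
22,-0.74,-0.33
20,-0.46,-0.14
18,-0.21,0.06
16,0.04,0.27
14,0.29,0.48
12,0.55,0.72
10,0.83,0.99
8,1.17,1.30
6,1.58,1.70
4,2.16,2.25
2,3.12,3.17
0,4.58,4.59
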