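grid_value,n_regular,n_irregular,n_stopped
38,5,0,0
39,33,2,2
40,86,6,5
41,79,10,2
42,87,7,5
43,99,8,9
44,98,14,14
45,78,19,19
46,86,13,23
47,83,17,24
48,58,19,28
49,47,26,45
50,32,27,52
51,32,20,77
52,27,23,93
53,13,14,101
54,8,8,122
55,9,0,135
56,3,3,116
57,2,1,131
58,6,0,129
59,7,0,120
60,12,0,115
61,8,1,131
62,9,0,158
63,6,0,96
64,4,0,86
65,0,0,13
66,0,0,1
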