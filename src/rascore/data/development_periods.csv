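grid_value,n_regular,n_irregular,n_stopped
0,0,0,1742
1,1,1,34
2,2,10,26
3,3,9,11
4,5,18,10
5,3,15,7
6,6,14,5
7,6,24,5
8,13,17,6
9,13,23,3
10,24,28,1
11,66,22,1
12,779,31,1
13,61,6,0
14,23,8,0
15,12,12,0
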