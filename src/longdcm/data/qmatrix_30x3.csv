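item,A1,A2,A3
1,1,0,0
2,0,1,0
3,0,0,1
4,1,1,0
5,1,0,1
6,0,1,1
7,1,0,0
8,0,1,0
9,0,0,1
10,1,1,0
11,1,0,1
12,0,1,1
13,1,0,0
14,0,1,0
15,0,0,1
16,1,1,0
17,1,0,1
18,0,1,1
19,1,0,0
20,0,1,0
21,0,0,1
22,1,1,0
23,1,0,1
24,0,1,1
25,1,0,0
26,0,1,0
27,0,0,1
28,1,1,0
29,1,0,1
30,0,1,1
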