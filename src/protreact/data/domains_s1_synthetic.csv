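index,domain,prohapten_flag
1,SNAr,
2,SN2,
3,Michael acceptor,
4,Acyl transfer,
5,Michael acceptor,
6,Acyl transfer,
7,SN2,
8,Michael acceptor,
9,Michael acceptor,
10,Schiff base,pro
11,Schiff base,
12,Schiff base,
13,Schiff base,
14,Schiff base,
15,Michael acceptor,
16,Michael acceptor,
17,SN2,
18,SN2,
19,Michael acceptor,
20,Michael acceptor,
21,None/SN2,
22,Michael acceptor,
23,Michael acceptor,
24,Michael acceptor,pro/pre
25,Michael acceptor,
26,Michael acceptor,
27,Michael acceptor/none,
28,Acyl transfer,
29,SN2,
30,SN2,
31,Schiff base/none,pro/pre
32,Michael acceptor,
33,Michael acceptor,
34,Michael acceptor,
35,Schiff base,pro
36,Michael acceptor,
37,Michael acceptor,pre/pro
38,None/SN2,
39,Michael acceptor,
40,Acyl transfer,
41,Acyl transfer,
42,Schiff base,
43,Michael acceptor,
44,Acyl transfer,
45,Acyl transfer,
46,SN2,
47,Acyl transfer,
48,SN2,
49,Michael acceptor/none,
50,Schiff base,
51,None,
52,None,
53,Michael acceptor,
54,Michael acceptor/none,
55,None,pro
56,None,
57,Michael acceptor,
58,Michael acceptor,
59,Michael acceptor,
60,Schiff base,pro/pre
61,None,
62,Schiff base,
63,Acyl transfer,
64,Schiff base,
65,None,pre
66,Michael acceptor,
67,Michael acceptor,pro
68,Michael acceptor,
69,None,
70,Michael acceptor,
71,Schiff base,
72,Michael acceptor,
73,None,
74,None,
75,None,
76,None,
77,Michael acceptor,
78,None,
79,None,pre
80,SNAr,
81,None,
82,None,
83,None,
84,None,
85,Schiff base/none,
86,None,
87,None,
88,Schiff base,
89,Schiff base,
90,None,
91,Schiff base,
92,None,
93,None,
94,None,
95,None,
96,None,
97,None,
98,None,
99,None,
100,None,
101,None,
102,None,
103,None,
104,None,
105,None,
106,None,
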