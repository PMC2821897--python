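age,qx
0,6.000000e-03
1,6.329898e-04
2,6.362775e-04
3,6.398929e-04
4,6.438685e-04
5,6.482404e-04
6,6.530480e-04
7,6.583347e-04
8,6.641483e-04
9,6.705412e-04
10,6.775713e-04
11,6.853020e-04
12,6.938031e-04
13,7.031514e-04
14,7.134313e-04
15,7.247357e-04
16,7.371668e-04
17,7.508366e-04
18,7.658688e-04
19,7.823991e-04
20,8.005768e-04
21,8.205661e-04
22,8.425475e-04
23,8.667195e-04
24,8.933004e-04
25,9.225304e-04
26,9.546734e-04
27,9.900198e-04
28,1.028889e-03
29,1.071631e-03
30,1.118633e-03
31,1.170320e-03
32,1.227157e-03
33,1.289659e-03
34,1.358390e-03
35,1.433970e-03
36,1.517082e-03
37,1.608478e-03
38,1.708982e-03
39,1.819501e-03
40,1.941036e-03
41,2.074682e-03
42,2.221647e-03
43,2.383258e-03
44,2.560976e-03
45,2.756404e-03
46,2.971309e-03
47,3.207631e-03
48,3.467504e-03
49,3.753277e-03
50,4.067529e-03
51,4.413098e-03
52,4.793107e-03
53,5.210988e-03
54,5.670514e-03
55,6.175835e-03
56,6.731516e-03
57,7.342576e-03
58,8.014534e-03
59,8.753458e-03
60,9.566022e-03
61,1.045957e-02
62,1.144216e-02
63,1.252268e-02
64,1.371088e-02
65,1.501749e-02
66,1.645432e-02
67,1.803434e-02
68,1.977183e-02
69,2.168247e-02
70,2.378353e-02
71,2.609397e-02
72,2.863467e-02
73,3.142858e-02
74,3.450092e-02
75,3.787945e-02
76,4.159467e-02
77,4.568015e-02
78,5.017279e-02
79,5.511316e-02
80,6.054588e-02
81,6.652001e-02
82,7.308953e-02
83,8.031375e-02
84,8.825793e-02
85,9.699382e-02
86,1.066003e-01
87,1.171642e-01
88,1.287808e-01
89,1.415552e-01
90,1.556026e-01
91,1.710500e-01
92,1.880369e-01
93,2.067166e-01
94,2.272580e-01
95,2.498464e-01
96,2.746860e-01
97,3.020012e-01
98,3.320384e-01
99,3.650692e-01
100,4.013918e-01
101,4.413343e-01
102,4.852573e-01
103,5.335577e-01
104,5.866717e-01
105,6.450789e-01
106,7.093069e-01
107,7.799359e-01
108,8.576036e-01
109,9.430116e-01
110,1.000000e+00
111,1.000000e+00
112,1.000000e+00
113,1.000000e+00
114,1.000000e+00
115,1.000000e+00
116,1.000000e+00
117,1.000000e+00
118,1.000000e+00
119,1.000000e+00
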