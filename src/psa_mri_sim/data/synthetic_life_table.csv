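age,qx
0,0.0003313683969
1,0.0003343954907
2,0.0003377142794
3,0.0003413528699
4,0.0003453420772
5,0.0003497156856
6,0.0003545107339
7,0.0003597678298
8,0.000365531493
9,0.0003718505324
10,0.000378778459
11,0.0003863739389
12,0.0003947012895
13,0.000403831024
14,0.0004138404479
15,0.0004248143131
16,0.0004368455343
17,0.0004500359756
18,0.0004644973114
19,0.0004803519708
20,0.0004977341727
21,0.0005167910599
22,0.0005376839432
23,0.0005605896635
24,0.0005857020862
25,0.000613233738
26,0.0006434176009
27,0.0006765090787
28,0.0007127881517
29,0.0007525617376
30,0.0007961662787
31,0.000843970577
32,0.0008963788997
33,0.0009538343821
34,0.001016822755
35,0.001085876427
36,0.001161578959
37,0.001244569958
38,0.001335550447
39,0.001435288729
40,0.001544626827
41,0.001664487513
42,0.001795882017
43,0.001939918455
44,0.002097811055
45,0.002270890243
46,0.002460613678
47,0.002668578319
48,0.002896533611
49,0.0031463959
50,0.00342026417
51,0.003720437242
52,0.004049432538
53,0.004410006559
54,0.004805177214
55,0.005238248169
56,0.005712835361
57,0.006232895869
58,0.006802759321
59,0.007427162037
60,0.008111284104
61,0.008860789613
62,0.009681870256
63,0.01058129253
64,0.01156644876
65,0.01264541218
66,0.01382699626
67,0.01512081857
68,0.01653736922
69,0.01808808425
70,0.01978542385
71,0.0216429557
72,0.0236754433
73,0.02589893919
74,0.028330883
75,0.03099020379
76,0.03389742626
77,0.03707478015
78,0.04054631165
79,0.04433799559
80,0.0484778467
81,0.0529960277
82,0.05792495143
83,0.06329937381
84,0.06915647325
85,0.0755359117
86,0.08247987113
87,0.09003305854
88,0.09824267074
89,0.1071583094
90,0.1168318347
91,0.1273171451
92,0.1386698676
93,0.1509469434
94,0.1642060896
95,0.1785051196
96,0.1939010989
97,0.2104493193
98,0.2282020678
99,0.2472071746
100,1
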