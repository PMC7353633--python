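sample_id,univariate_measured,univariate_variance_adjusted,knn_measured,knn_variance_adjusted
1,7,4,yes,no
2,7,3,yes,no
3,7,0,yes,no
4,6,3,yes,no
5,6,2,yes,no
6,6,1,yes,no
7,6,0,yes,no
8,6,0,yes,no
9,6,0,yes,no
10,6,0,yes,no
11,6,0,yes,no
12,5,3,yes,no
13,5,1,yes,no
14,5,1,yes,no
15,5,0,yes,no
16,5,0,yes,no
17,5,0,no,no
18,4,1,yes,no
19,4,1,yes,no
20,4,0,yes,no
21,3,1,yes,no
22,3,0,yes,no
23,3,0,no,no
24,3,0,no,no
25,2,0,no,no
26,1,1,yes,no
27,1,0,yes,no
28,1,0,yes,no
29,1,0,no,no
30,1,0,no,no
31,1,0,no,no
32,1,0,no,no
33,1,0,no,no
34,1,0,no,no
35,1,0,no,no
36,1,0,no,no
37,1,0,no,no
38,0,0,yes,yes
39,0,0,yes,yes
40,0,0,yes,no
41,0,0,yes,no
42,0,0,yes,no
43,0,0,no,yes
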