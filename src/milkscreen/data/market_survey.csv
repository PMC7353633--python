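sample_id,protein,fat,ts,snf,lactose,density,fpd,area,province
1,3.09,3.56,12.06,8.42,4.58,1029,0.488,N,Tianjin
2,3.07,3.48,11.94,8.37,4.55,1029,0.490,NW,Xinjiang
3,3.28,3.49,12.25,8.69,4.65,1030,0.515,NW,Xinjiang
4,3.05,3.79,12.35,8.51,4.71,1029,0.498,N,Henan
5,3.12,3.61,12.18,8.50,4.62,1030,0.492,N,Tianjin
6,2.99,3.43,12.06,8.58,4.85,1030,0.512,E,Zhejiang
7,3.14,3.70,12.32,8.56,4.67,1030,0.494,N,Henan
8,3.28,3.74,12.49,8.68,4.64,1030,0.513,NW,Xinjiang
9,3.17,3.87,12.54,8.62,4.69,1030,0.505,NW,Xinjiang
10,3.22,3.40,12.19,8.72,4.74,1031,0.497,S,Chongqing
11,3.33,3.60,12.39,8.73,4.63,1030,0.492,S,Yunnan
12,2.95,3.05,11.78,8.69,4.99,1031,0.510,E,Jiangsu
13,3.14,4.16,12.75,8.55,4.65,1029,0.496,N,Tianjin
14,3.03,3.57,12.34,8.74,4.96,1031,0.513,S,Yunnan
15,3.17,3.40,12.29,8.85,4.93,1031,0.510,N,Shanxi
16,3.15,4.15,12.81,8.62,4.70,1030,0.500,NW,Xinjiang
17,3.27,3.53,12.41,8.83,4.80,1031,0.514,S,Yunnan
18,3.01,3.63,12.26,8.58,4.81,1028,0.538,S,Hubei
19,3.12,3.51,12.47,8.95,5.07,1032,0.513,S,Yunnan
20,3.25,4.21,13.05,8.81,4.80,1030,0.505,N,Hebei
21,3.12,4.06,12.86,8.78,4.91,1030,0.523,NW,Shaanxi
22,3.25,3.31,12.32,8.97,4.96,1032,0.520,N,Beijing
23,3.37,4.16,13.09,8.89,4.75,1030,0.525,NW,Gansu
24,3.30,3.47,12.50,8.99,4.94,1032,0.523,S,Guangdong
25,3.26,3.58,12.67,9.07,5.06,1032,0.531,N,Hebei
26,3.09,3.75,12.76,9.00,5.16,1032,0.541,E,Shandong
27,3.26,4.23,13.24,9.00,4.97,1031,0.570,NW,Qinghai
28,3.32,3.97,13.24,9.29,5.21,1033,0.536,S,Yunnan
29,3.29,3.84,12.91,9.05,5.00,1032,0.538,E,Shandong
30,3.29,3.83,12.94,9.06,5.05,1032,0.532,N,Beijing
31,3.30,3.91,12.95,9.03,4.97,1032,0.524,N,Hebei
32,3.63,3.88,13.67,9.83,5.42,1035,0.573,NE,Heilongjiang
33,3.34,3.57,12.73,9.13,5.03,1032,0.524,NW,Ningxia
34,3.26,3.99,13.10,9.11,5.08,1032,0.539,NW,Xinjiang
35,3.32,3.97,13.17,9.19,5.11,1032,0.538,S,Chongqing
36,3.28,3.63,12.67,9.01,4.97,1032,0.530,S,Guangdong
37,3.58,3.85,13.57,9.74,5.40,1035,0.566,S,Guangdong
38,3.47,4.32,13.73,9.44,5.21,1033,0.546,E,Jiangsu
39,3.60,3.86,13.40,9.55,5.18,1033,0.553,NE,Heilongjiang
40,3.55,4.20,13.55,9.35,5.02,1032,0.540,E,Shandong
41,3.40,3.72,13.08,9.36,5.20,1033,0.548,NW,Xinjiang
42,3.40,4.40,13.56,9.16,4.99,1032,0.536,S,Guizhou
43,3.51,4.22,13.83,9.65,5.36,1034,0.560,N,Hebei
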