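id,cag,motor_onset,age1,status1,uhdrs1,ei1,age2,status2,uhdrs2,ei2,age3,status3,uhdrs3,ei3,er,ei_ao,ao_group,age_death
1,39,49,39,P,0,0.1187,50,M,7,0.1369,NA,NA,NA,NA,0.00166,0.1355,Earlier,NA
2,40,58,40,P,0,0.1591,58,M,17,0.1910,NA,NA,NA,NA,0.00177,0.1908,Later,NA
3,40,80,76,M,0,0.2048,87,M,36,0.2499,NA,NA,NA,NA,0.00409,0.2210,Later,91
4,41,44,46,M,0,0.2120,65,M,34,0.3970,69,M,75,0.4265,0.00946,0.1941,Earlier,77
5,41,37,28,M,0,0.2929,42,M,27,0.3806,45,M,42,0.4274,0.0074,0.2905,Earlier,NA
6,42,39,32,P,0,0.1688,46,M,28,0.2173,53,M,18,0.3446,0.00767,0.2079,Earlier,NA
7,42,42,32,P,0,0.1968,39,P,0,0.2917,51,M,25,0.3596,0.00826,0.2939,Earlier,NA
8,42,43,34,P,0,0.1991,47,M,31,0.3387,NA,NA,NA,NA,0.01074,0.2959,As expected,NA
9,42,45,39,P,0,0.2145,52,M,22,0.2380,NA,NA,NA,NA,0.00181,0.2255,As expected,NA
10,42,48,50,M,21,0.2982,59,M,76,0.3596,61,M,76,0.3264,0.00386,0.2943,As expected,66
11,42,50,51,M,18,0.1943,59,M,39,0.2606,NA,NA,NA,NA,0.00829,0.1859,As expected,NA
12,42,50,50,P,4,0.4070,61,M,40,0.4239,NA,NA,NA,NA,0.00154,0.4072,As expected,NA
13,42,60,62,M,45,0.3774,73,M,78,0.4249,NA,NA,NA,NA,0.00432,0.3685,Later,74
14,42,57,56,M,0,0.3981,70,M,70,0.4905,NA,NA,NA,NA,0.0066,0.3980,Later,NA
15,42,56,60,M,20,0.4311,68,M,45,0.4581,NA,NA,NA,NA,0.00338,0.4176,Later,75
16,42,61,63,M,36,0.4569,65,M,53,0.4563,NA,NA,NA,NA,-0.0003,0.4576,Later,NA
17,43,37,29,P,0,0.1806,53,M,31,0.3641,NA,NA,NA,NA,0.00765,0.2418,Earlier,NA
18,43,45,43,P,0,0.3159,59,M,40,0.4275,NA,NA,NA,NA,0.00698,0.3299,As expected,NA
19,43,45,37,P,0,0.2879,52,M,38,0.4628,54,M,43,0.5088,0.01249,0.3865,As expected,NA
20,43,47,46,P,0,0.3255,56,M,32,0.4228,NA,NA,NA,NA,0.00973,0.3351,As expected,64
21,43,47,50,M,18,0.4430,58,M,57,0.5164,NA,NA,NA,NA,0.00917,0.4153,As expected,NA
22,44,48,21,P,0,0.1731,29,P,0,0.2063,47,M,18,0.2866,0.00438,0.2862,Later,NA
23,44,56,39,P,0,0.2002,62,M,38,0.4136,NA,NA,NA,NA,0.00928,0.3581,Later,NA
24,44,44,32,P,0,0.2176,35,P,0,0.2214,NA,NA,NA,NA,0.00127,0.2327,As expected,56
25,44,44,25,P,0,0.2162,42,M,12,0.5379,NA,NA,NA,NA,0.01892,0.5377,As expected,NA
26,44,37,31,P,0,0.3739,44,M,32,0.5477,NA,NA,NA,NA,0.01337,0.4541,Earlier,49
27,44,44,37,P,0,0.3635,50,P,0,0.4687,NA,NA,NA,NA,0.00809,0.4201,As expected,57
28,44,37,28,P,0,0.3751,43,M,35,0.5175,NA,NA,NA,NA,0.00949,0.4604,Earlier,NA
29,44,50,42,P,0,0.4229,54,M,38,0.5162,NA,NA,NA,NA,0.00778,0.4851,Later,NA
30,44,26,26,M,11,0.4279,36,M,22,0.5113,NA,NA,NA,NA,0.00834,0.4279,Earlier,NA
31,44,46,49,M,NA,0.4550,60,M,86,0.5854,NA,NA,NA,NA,0.01185,0.4193,As expected,61
32,44,30,36,P,0,0.4272,50,M,49,0.5667,NA,NA,NA,NA,0.00997,0.3674,Earlier,54
33,45,37,20,P,0,0.3551,38,M,7,0.5407,NA,NA,NA,NA,0.01031,0.5303,As expected,NA
34,45,40,35,P,0,0.4522,49,M,52,0.6794,51,M,55,0.7050,0.01596,0.5325,As expected,NA
35,45,40,46,M,NA,0.7408,58,M,NA,1.0457,NA,NA,NA,NA,0.02541,0.5884,As expected,NA
36,46,40,27,P,0,0.2948,48,M,43,0.6126,NA,NA,NA,NA,0.01514,0.4917,As expected,NA
37,46,36,26,P,0,0.5122,39,M,58,0.7044,NA,NA,NA,NA,0.01478,0.6599,As expected,NA
38,46,35,35,P,0,0.6031,45,M,91,0.7675,NA,NA,NA,NA,0.01645,0.6031,As expected,49
39,46,45,47,M,18,0.7701,55,M,59,0.9431,NA,NA,NA,NA,0.02163,0.7270,Later,NA
40,47,36,46,M,45,1.5687,57,M,92,2.6750,NA,NA,NA,NA,0.10057,0.5629,As expected,64
41,48,30,21,P,0,0.7800,38,M,57,1.6341,NA,NA,NA,NA,0.05024,1.2321,Earlier,39
42,48,32,33,M,8,0.9630,43,M,84,1.2162,53,M,92,1.8055,0.04213,0.8650,As expected,NA
43,49,39,29,P,0,1.2709,42,M,84,1.7097,42,NA,NA,1.7208,0.03419,1.6129,Later,NA
44,49,27,20,P,0,0.8439,27,M,63,1.3535,NA,NA,NA,NA,0.0728,1.3534,Earlier,NA
45,49,33,41,M,43,1.6512,43,M,53,1.9788,51,M,70,2.6855,0.09912,0.9159,As expected,NA
46,50,25,31,M,NA,2.7278,41,M,NA,3.6178,NA,NA,NA,NA,0.089,2.1936,Earlier,NA
47,52,25,20,P,0,0.8479,33,M,32,1.7060,39,M,69,2.0014,0.06156,1.1696,Earlier,NA
48,52,27,36,M,NA,3.1542,36,M,49,3.3273,NA,NA,NA,NA,NA,NA,As expected,NA
49,53,26,26,M,15,1.9819,34,M,22,3.0756,NA,NA,NA,NA,0.13672,1.982,As expected,NA
50,54,36,20,P,0,1.9449,36,M,13,3.8745,NA,NA,NA,NA,0.1206,3.8745,Later,NA
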