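id,sex,cag,ei,age_death
1,F,40,1.4506,74
2,F,41,1.3197,84
3,F,42,3.2444,75
4,M,43,1.6834,55
5,M,43,2.6007,68
6,F,44,1.2883,NA
7,M,44,3.2551,41
8,F,44,3.0440,59
9,F,44,3.7083,55
10,F,45,2.9722,59
11,F,46,1.5191,43
12,F,47,9.0942,43
13,M,48,2.8506,41
14,F,50,3.7961,58
15,F,50,8.5912,45
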