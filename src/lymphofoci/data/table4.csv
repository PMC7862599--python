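case,age,sex,abnormal_pct,t1118,trisomy18q21,eradication,radiation,response
1,69,M,67.7,+,+,+,-,-
2,69,M,34.1,+,+,+,-,-
3,74,M,42.9,+,-,-,-,-
4,56,M,36.9,+,-,-,+,+
5,68,M,34.1,+,-,-,+,+
6,47,F,19.1,+,-,+,-,+
7,59,M,44.2,-,+/-,ND,ND,ND
8,87,M,26.5,-,-,-,-,+
9,59,M,26.5,-,-,ND,ND,ND
10,66,M,19.4,-,-,-,+,+
11,42,F,18,-,-,+,-,-
12,58,M,17.2,-,-,+,-,DT
13,74,F,15,-,-,+,-,+
14,50,M,13.9,-,-,ND,ND,ND
15,59,M,11.4,-,-,+,-,-
16,62,M,10.3,-,-,-,+,+
17,51,F,13.7,NS,NS,+,-,+
18,67,F,15.2,NS,NS,-,+,+
19,65,M,24.1,NS,NS,ND,ND,ND
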