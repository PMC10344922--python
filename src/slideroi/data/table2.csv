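case,user1_score,user1_status,user2_score,user2_status
1,2.50,Pos,2.45,Pos
2,2.45,Pos,2.36,Pos
3,2.22,Pos,3.02,Pos
4,3.83,Pos,6.33,Pos
5,2.14,Pos,1.81,Neg
6,2.64,Pos,1.65,Neg
7,2.57,Pos,1.24,Neg
8,4.26,Pos,1.45,Neg
9,4.15,Pos,2.37,Pos
10,4.24,Pos,6.73,Pos
11,1.30,Neg,4.16,Pos
12,2.65,Pos,6.70,Pos
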