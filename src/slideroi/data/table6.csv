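case,clinical_score,clinical_status,user1_score,user1_status,user2_score,user2_status,proposed_score,proposed_status
1,0.97,Neg,2.50,Pos,2.45,Pos,1.09,Neg
2,5.50,Pos,2.45,Pos,2.36,Pos,5.20,Pos
3,2.12,Pos,2.22,Pos,3.02,Pos,2.22,Pos
4,2.37,Pos,3.83,Pos,6.33,Pos,2.40,Pos
5,2.17,Pos,2.14,Pos,1.81,Neg,2.14,Pos
6,1.65,Neg,2.64,Pos,1.75,Neg,1.62,Neg
7,1.27,Neg,2.57,Pos,1.24,Neg,1.29,Neg
8,1.45,Neg,4.26,Pos,1.67,Neg,1.56,Neg
9,2.57,Pos,4.15,Pos,2.37,Pos,2.63,Pos
10,1.25,Neg,4.24,Pos,6.73,Pos,1.20,Neg
11,1.20,Neg,1.30,Neg,4.16,Pos,1.17,Neg
12,2.36,Pos,2.65,Pos,6.70,Pos,2.46,Pos
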