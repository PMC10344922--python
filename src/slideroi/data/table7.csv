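case,test_score,test_status,retest_score,retest_status
1,1.09,Neg,1.00,Neg
2,5.20,Pos,5.15,Pos
3,2.22,Pos,2.22,Pos
4,2.40,Neg,2.49,Neg
5,2.14,Neg,2.10,Neg
6,1.62,Neg,1.56,Neg
7,1.29,Neg,1.20,Neg
8,1.56,Neg,1.47,Neg
9,2.63,Pos,2.70,Pos
10,1.20,Neg,1.13,Neg
11,1.17,Neg,1.09,Neg
12,2.46,Pos,2.52,Pos
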