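locus,allele,epitopes
A,A*01,
A,A*02,
A,A*03,A3A11
A,A*11,A3A11
A,A*23,A_BW4
A,A*24,A_BW4
A,A*25,A_BW4
A,A*26,
A,A*29,
A,A*30,
A,A*31,
A,A*32,A_BW4
A,A*33,
A,A*34,
A,A*36,
A,A*66,
A,A*68,
A,A*69,
A,A*74,
A,A*80,
B,B*07,
B,B*08,
B,B*13,BW4_T80
B,B*14,
B,B*15,
B,B*15:13,BW4_I80
B,B*15:16,BW4_T80
B,B*15:17,BW4_T80
B,B*18,
B,B*27,BW4_T80
B,B*27:02,BW4_I80
B,B*35,
B,B*37,BW4_T80
B,B*38,BW4_I80
B,B*39,
B,B*40,
B,B*41,
B,B*42,
B,B*44,BW4_T80
B,B*45,
B,B*47,BW4_T80
B,B*48,
B,B*49,BW4_I80
B,B*50,
B,B*51,BW4_I80
B,B*52,BW4_I80
B,B*53,BW4_I80
B,B*54,
B,B*55,
B,B*56,
B,B*57,BW4_I80
B,B*58,BW4_I80
B,B*59,BW4_I80
C,C*01,C1
C,C*02,C2
C,C*03,C1
C,C*04,C2
C,C*05,C2
C,C*06,C2
C,C*07,C1
C,C*08,C1
C,C*12,C1
C,C*14,C1
C,C*15,C2
C,C*16,C1
C,C*16:02,C2
C,C*17,C2
C,C*18,C2
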