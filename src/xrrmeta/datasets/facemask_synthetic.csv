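label,y1,n1,y2,n2
synthetic_1,3,681,33,472
synthetic_2,2,51,14,99
synthetic_3,16,510,32,507
synthetic_4,17,452,37,346
synthetic_5,0,33,3,24
synthetic_6,5,124,5,97
synthetic_7,3,215,14,142
synthetic_8,1,126,9,153
synthetic_9,2,298,26,471
synthetic_10,4,88,13,102
synthetic_11,3,42,4,42
synthetic_12,0,117,14,146
synthetic_13,0,48,4,51
synthetic_14,3,90,20,179
synthetic_15,2,50,10,83
synthetic_16,2,36,1,65
synthetic_17,1,62,1,33
synthetic_18,6,433,25,323
synthetic_19,3,123,1,117
synthetic_20,2,615,43,394
synthetic_21,4,277,12,154
synthetic_22,3,205,8,137
synthetic_23,0,34,1,17
synthetic_24,7,469,93,873
synthetic_25,2,138,4,73
synthetic_26,7,277,17,186
synthetic_27,1,72,9,80
synthetic_28,2,196,18,394
synthetic_29,2,104,2,82
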