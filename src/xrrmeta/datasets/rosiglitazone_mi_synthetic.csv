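label,y1,n1,y2,n2
synthetic_1,0,119,0,60
synthetic_2,5,448,0,224
synthetic_3,3,449,0,224
synthetic_4,2,306,1,306
synthetic_5,3,201,1,201
synthetic_6,0,248,1,124
synthetic_7,1,330,2,165
synthetic_8,6,228,0,114
synthetic_9,1,282,1,282
synthetic_10,3,1501,15,2502
synthetic_11,1,123,0,62
synthetic_12,1,114,1,57
synthetic_13,1,130,2,130
synthetic_14,1,102,0,102
synthetic_15,28,2635,11,2634
synthetic_16,0,105,0,105
synthetic_17,1,121,0,121
synthetic_18,0,146,0,146
synthetic_19,5,438,1,219
synthetic_20,0,167,0,84
synthetic_21,2,139,0,70
synthetic_22,0,126,0,126
synthetic_23,1,175,0,88
synthetic_24,0,327,1,164
synthetic_25,0,385,0,192
synthetic_26,2,161,0,80
synthetic_27,0,321,1,160
synthetic_28,2,130,2,65
synthetic_29,0,183,0,183
synthetic_30,2,306,1,306
synthetic_31,2,216,0,108
synthetic_32,0,105,0,52
synthetic_33,0,133,0,133
synthetic_34,2,333,0,166
synthetic_35,0,160,1,160
synthetic_36,4,149,0,149
synthetic_37,1,284,0,284
synthetic_38,2,351,1,176
synthetic_39,6,313,1,313
synthetic_40,0,161,0,80
synthetic_41,0,180,0,180
synthetic_42,0,113,2,113
synthetic_43,2,1456,5,2895
synthetic_44,0,105,1,105
synthetic_45,0,300,0,150
synthetic_46,0,132,0,66
synthetic_47,2,252,2,126
synthetic_48,2,173,0,173
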