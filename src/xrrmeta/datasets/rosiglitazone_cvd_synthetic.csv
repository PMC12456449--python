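label,y1,n1,y2,n2
synthetic_1,0,119,0,60
synthetic_2,1,448,0,224
synthetic_3,0,449,0,224
synthetic_4,0,306,0,306
synthetic_5,1,201,1,201
synthetic_6,1,248,0,124
synthetic_7,3,330,0,165
synthetic_8,2,228,0,114
synthetic_9,1,282,0,282
synthetic_10,8,1501,0,2502
synthetic_11,1,123,0,62
synthetic_12,0,114,0,57
synthetic_13,0,130,1,130
synthetic_14,0,102,0,102
synthetic_15,14,2635,0,2634
synthetic_16,1,105,0,105
synthetic_17,0,121,0,121
synthetic_18,0,146,1,146
synthetic_19,4,438,0,219
synthetic_20,1,167,0,84
synthetic_21,0,139,0,70
synthetic_22,0,126,0,126
synthetic_23,1,175,0,88
synthetic_24,0,327,0,164
synthetic_25,1,385,0,192
synthetic_26,1,161,2,80
synthetic_27,1,321,0,160
synthetic_28,0,130,0,65
synthetic_29,1,183,0,183
synthetic_30,3,306,0,306
synthetic_31,1,216,1,108
synthetic_32,0,105,0,52
synthetic_33,0,133,0,133
synthetic_34,0,333,0,166
synthetic_35,0,160,0,160
synthetic_36,1,149,0,149
synthetic_37,0,284,0,284
synthetic_38,3,351,3,176
synthetic_39,0,313,0,313
synthetic_40,1,161,1,80
synthetic_41,2,180,0,180
synthetic_42,0,113,0,113
synthetic_43,6,1456,2,2895
synthetic_44,0,105,0,105
synthetic_45,2,300,0,150
synthetic_46,1,132,0,66
synthetic_47,1,252,0,126
synthetic_48,0,173,0,173
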