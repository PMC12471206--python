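variable,value
a,5320000000.0
mq,5440000.0
cq,2610000.0
q,3200000000.0
mL,51300.0
mS,122000000.0
cL,180000.0
O1,27800000.0
bL,2830.0
bS,5640.0
L,1070.0
S,13400.0
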