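,T1,T3,T2,T5,T4,T13,T9,T15,T10
T1,18,1,0,0,0,2,2,0,1
T3,0,5,0,0,0,0,0,0,0
T2,1,0,6,0,0,0,0,0,0
T5,0,1,0,2,0,0,0,0,1
T4,0,0,0,0,2,0,0,0,0
T13,1,0,0,0,0,1,0,0,0
T9,0,1,0,0,0,1,2,0,1
T15,3,0,0,0,0,0,0,2,1
T10,0,1,0,0,0,0,0,0,1
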