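,T1,T3,T2,T5,T4,T13,T9,T15,T10
T1,22,1,0,0,0,2,2,0,2
T3,0,6,0,0,0,0,1,0,0
T2,1,0,6,0,0,0,0,0,0
T5,0,1,0,2,0,0,0,0,0
T4,0,0,0,0,2,0,0,0,1
T13,0,0,0,0,0,1,0,0,1
T9,0,0,0,0,0,1,1,0,0
T15,0,0,0,0,0,0,0,2,0
T10,0,1,0,0,0,0,0,0,1
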