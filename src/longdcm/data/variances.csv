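effect,variance
u0_A1,0.15
u1_A1,0.05
u0_A2,0.15
u1_A2,0.05
u0_A3,0.15
u1_A3,0.05
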