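,u0_A1,u1_A1,u0_A2,u1_A2,u0_A3,u1_A3
u0_A1,1.00,0.10,0.90,0.01,0.90,0.01
u1_A1,0.10,1.00,0.01,0.01,0.01,0.01
u0_A2,0.90,0.01,1.00,0.20,0.90,0.10
u1_A2,0.01,0.01,0.20,1.00,0.10,0.25
u0_A3,0.90,0.01,0.90,0.10,1.00,0.20
u1_A3,0.01,0.01,0.10,0.25,0.20,1.00
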