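attribute,gamma00,gamma10
A1,-1.38,0.00
A2,-1.10,0.04
A3,-0.85,0.05
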