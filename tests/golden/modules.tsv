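gene	module
CD33	4
M1_g0	0
M1_g1	0
M1_g2	0
M1_g3	0
M2_g0	1
M2_g1	1
M2_g2	1
M3_g0	2
M3_g1	2
M3_g2	2
M4_g0	3
M4_g1	3
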