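from	to
CD33	M1
CD33	M3
M1	M2
M1	M3
M2	M3
M2	phenotype
M3	M4
M3	phenotype
age	CD33
education	M4
education	phenotype
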