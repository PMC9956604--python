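from	to	support
0	1	7
2	3	6
4	0	9
4	2	6
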