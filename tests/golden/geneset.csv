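gene_set,n_genes,Q,p,note,q
CD33,1,110820.5324,0.000999000999,,0.000999000999
M1,4,83987.42547,0.000999000999,,0.000999000999
M2,3,57586.95381,0.000999000999,,0.000999000999
M3,3,68112.71119,0.000999000999,,0.000999000999
M4,2,18627.2094,0.000999000999,,0.000999000999
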