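pathway	n_genes	n_genes_with_pvs	n_pvs
Homologous Recombination	37	21	472
DNA damage response	15	4	66
Fanconi anemia	49	30	493
Mismatch Repair	20	9	134
Nonhomologous end joining	13	6	72
Nucleotide excision repair	41	15	121
Base excision repair	32	8	63
DNA replication	34	12	35
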