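locus	n_alleles
A	47
B	73
C	35
DPA1	11
DPB1	39
DQA1	8
DQB1	25
DRB1	45
DRB5	2
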